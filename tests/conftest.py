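import pytest

from ogbkit import PoreRegime, load_fixture_catalog, load_reference_degassing


# Published per-sample indicator values (replicate means) and regime
# assignments for the six study fractions, plus their compaction
# coefficients. Used as recomputation targets throughout the suite.
STUDY_ROWS = {
    "Xenograft Collagen": dict(W_mA=129.27, W_mB=87.47, AC_A=0.997, AC_T=0.895,
                               regime=PoreRegime.MIXED, C_C=1.24),
    "Osteon II":          dict(W_mA=93.63, W_mB=31.73, AC_A=0.803, AC_T=0.803,
                               regime=PoreRegime.MACRO, C_C=1.69),
    "Maxresorb":          dict(W_mA=115.10, W_mB=41.93, AC_A=0.753, AC_T=0.753,
                               regime=PoreRegime.MACRO, C_C=1.28),
    "MSP":                dict(W_mA=80.12, W_mB=28.60, AC_A=0.681, AC_T=0.681,
                               regime=PoreRegime.MACRO, C_C=1.03),
    "Cerabone":           dict(W_mA=59.13, W_mB=19.10, AC_A=0.563, AC_T=0.563,
                               regime=PoreRegime.MACRO, C_C=1.25),
    "Bio-OSS":            dict(W_mA=131.13, W_mB=59.00, AC_A=0.703, AC_T=0.386,
                               regime=PoreRegime.MICRO, C_C=1.02),
}

# Published logistic fit of the reference degassing series and the
# printed standard errors of its parameters.
REF_LOGISTIC = dict(a=0.51, b=10.10, c=81.01, d=100.0)
REF_LOGISTIC_SE = dict(a=0.04, b=0.17, c=0.35)


@pytest.fixture(scope="session")
def study_rows():
    return STUDY_ROWS


@pytest.fixture(scope="session")
def ref_degassing():
    return load_reference_degassing()


@pytest.fixture(scope="session")
def catalog_noiseless():
    return load_fixture_catalog(noise_sd=0.0)


@pytest.fixture(scope="session")
def catalog_default():
    return load_fixture_catalog(noise_sd=0.01)
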