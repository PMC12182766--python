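"""Seeded synthetic bench measurements for every pipeline stage.

The generators invert the indicator formulas: given target indicator
values for a named fraction (the six study materials ship as a packaged
catalog, plus user-defined fixtures), they reconstruct raw masses,
volumes and column heights that the forward pipeline maps back onto the
targets exactly at zero noise, then perturb the bench-measured quantities
with Gaussian replicate noise.

Noise placement follows the measurement process: the dry mass (weighed to
a nominal 2 g) and the dispensed initial volume V3 are protocol
constants, so replicate scatter enters through the recovered volumes
(V1, V2), the wet masses (m2, m3; m4, m5) and the column heights —
multiplicatively, with a relative SD (default 1 %).  Degassing series
instead get additive Gaussian noise on the percentage scale, matching the
roughly constant confidence-interval half-widths over time.

Every generator takes one explicit integer seed; no global RNG state.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import numpy as np

from .compaction import CompactionMeasurement
from .errors import ValidationError
from .indicators import PoreRegime, SampleMeasurement
from .kinetics import DegassingSeries, LogisticModel, logistic_value

__all__ = [
    "OgbFixture",
    "load_fixture_catalog",
    "load_reference_degassing",
    "synthesize_sample_measurements",
    "synthesize_compaction_measurements",
    "simulate_degassing_series",
]

# Share of AC_A released during the passive stage, from the reference
# two-stage measurement (0.38 mL of 0.56 mL).
DEFAULT_PASSIVE_SHARE = 0.38 / 0.56


@dataclass(frozen=True)
class OgbFixture:
    """Target indicator values defining one synthetic fraction."""

    name: str
    target_W_mA: float           # %
    target_W_mB: float           # %
    target_AC_A: float           # mL
    micropore_volume: float      # cm³/g
    regime: PoreRegime
    target_C_C: float = 1.0
    replicate_noise_sd: float = 0.01   # relative SD on noisy quantities
    passive_share: float = DEFAULT_PASSIVE_SHARE
    V3: float = 2.0              # mL
    m1: float = 2.0              # g

    def __post_init__(self) -> None:
        if self.target_AC_A < 0 or self.target_AC_A > self.V3:
            raise ValidationError(
                f"{self.name}: target_AC_A ({self.target_AC_A} mL) must lie in "
                f"[0, V3={self.V3} mL]"
            )
        if not (0 <= self.target_W_mB <= self.target_W_mA):
            raise ValidationError(
                f"{self.name}: target_W_mB must lie in [0, target_W_mA]"
            )
        if self.target_C_C < 1:
            raise ValidationError(
                f"{self.name}: target_C_C ({self.target_C_C}) must be >= 1"
            )
        if not (0 <= self.passive_share <= 1):
            raise ValidationError(f"{self.name}: passive_share must be in [0, 1]")
        if self.replicate_noise_sd < 0:
            raise ValidationError(f"{self.name}: replicate_noise_sd must be >= 0")


def _catalog_raw() -> dict:
    with resources.files("ogbkit").joinpath("data/fixtures.json").open("r") as fh:
        return json.load(fh)


def load_fixture_catalog(noise_sd: float = 0.01) -> dict[str, OgbFixture]:
    """The six study fractions with their published indicator targets."""
    out = {}
    for name, row in _catalog_raw()["fixtures"].items():
        out[name] = OgbFixture(
            name=name,
            target_W_mA=row["target_W_mA"],
            target_W_mB=row["target_W_mB"],
            target_AC_A=row["target_AC_A"],
            micropore_volume=row["micropore_volume"],
            regime=PoreRegime(row["regime"]),
            target_C_C=row["target_C_C"],
            replicate_noise_sd=noise_sd,
        )
    return out


def load_reference_degassing() -> dict:
    """Reference degassing summary: times, per-time means and 95 % CI bounds."""
    return _catalog_raw()["reference_degassing"]


def _rng(seed: int) -> np.random.Generator:
    if not isinstance(seed, (int, np.integer)):
        raise ValidationError(f"seed must be an integer, got {seed!r}")
    return np.random.default_rng(int(seed))


def synthesize_sample_measurements(
    fixture: OgbFixture, n_replicates: int, seed: int
) -> list[SampleMeasurement]:
    """Reconstruct raw adsorption-bench records hitting the fixture targets.

    Inversion: m2 = m1 (1 + W_mA/100), m3 = m1 (1 + W_mB/100),
    V2 = V3 − AC_A, V1 = V3 − passive_share · AC_A.  Multiplicative
    Gaussian noise is applied to m2, m3, V1, V2 per replicate.
    """
    if n_replicates < 1:
        raise ValidationError(f"n_replicates must be >= 1, got {n_replicates}")
    rng = _rng(seed)
    m1, V3 = fixture.m1, fixture.V3
    m2 = m1 * (1 + fixture.target_W_mA / 100.0)
    m3 = m1 * (1 + fixture.target_W_mB / 100.0)
    V2 = V3 - fixture.target_AC_A
    V1 = V3 - fixture.passive_share * fixture.target_AC_A
    sd = fixture.replicate_noise_sd
    out = []
    for _ in range(n_replicates):
        f = 1.0 + sd * rng.standard_normal(4) if sd > 0 else np.ones(4)
        out.append(
            SampleMeasurement(
                sample_id=fixture.name,
                m1=float(m1),
                m2=float(m2 * f[0]),
                m3=float(m3 * f[1]),
                V1=float(V1 * f[2]),
                V2=float(V2 * f[3]),
                V3=float(V3),
            )
        )
    return out


def synthesize_compaction_measurements(
    fixture: OgbFixture, n_replicates: int, seed: int
) -> list[CompactionMeasurement]:
    """Reconstruct compaction-bench records with C_C = target at zero noise.

    Construction: h2 = 1 cm, h1 = target_C_C (the coefficient reduces to
    h1/h2), r = 1 cm, m4 = m5 = m1 (1 + W_mA/100).  Noise is applied to
    m4, m5, h1, h2.
    """
    if n_replicates < 1:
        raise ValidationError(f"n_replicates must be >= 1, got {n_replicates}")
    rng = _rng(seed)
    m1 = fixture.m1
    m_sat = m1 * (1 + fixture.target_W_mA / 100.0)
    sd = fixture.replicate_noise_sd
    out = []
    for _ in range(n_replicates):
        f = 1.0 + sd * rng.standard_normal(4) if sd > 0 else np.ones(4)
        out.append(
            CompactionMeasurement(
                sample_id=fixture.name,
                m1=float(m1),
                m4=float(m_sat * f[0]),
                m5=float(m_sat * f[1]),
                h1=float(fixture.target_C_C * f[2]),
                h2=float(1.0 * f[3]),
                r=1.0,
            )
        )
    return out


def simulate_degassing_series(
    model: LogisticModel,
    times: Sequence[float],
    n_replicates: int,
    noise_sd: float,
    seed: int,
    sample_id: str = "synthetic",
) -> DegassingSeries:
    """Draw replicate degassing series from a logistic model.

    pct = f(t) + N(0, noise_sd²) per replicate, additive on the
    percentage scale; noise_sd = 0 reproduces the curve exactly.
    """
    if noise_sd < 0:
        raise ValidationError(f"noise_sd must be >= 0, got {noise_sd}")
    if n_replicates < 1:
        raise ValidationError(f"n_replicates must be >= 1, got {n_replicates}")
    rng = _rng(seed)
    times = np.asarray(list(times), dtype=float)
    points = []
    for rep in range(1, n_replicates + 1):
        vals = logistic_value(model, times)
        vals = np.atleast_1d(vals)
        if noise_sd > 0:
            vals = vals + noise_sd * rng.standard_normal(len(times))
        for t, v in zip(times, vals):
            points.append((float(t), float(v), rep))
    return DegassingSeries(sample_id=sample_id, points=tuple(points))
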