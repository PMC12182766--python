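"""Adsorption-capacity indicators of a granular bone-graft (OGB) fraction.

A dry granular osteoconductive biopolymer (OGB) sample of mass ``m1`` is
degassed in two stages (passive saline soak, then active ultrasonic
treatment in citric acid).  The liquid volumes recovered after each stage
(``V1``, ``V2``; initial volume ``V3``) and the sample masses before and
after draining the intergranular liquid (``m2``, ``m3``) yield:

* the apparent adsorption capacity ``AC_A = (V3 - V1) + (V1 - V2)`` —
  the liquid volume taken up by the fraction;
* water absorption by mass including intergranular spaces,
  ``W_mA = (m2 - m1) / m1 × 100 %``, and excluding them,
  ``W_mB = (m3 - m1) / m1 × 100 %``;
* the true adsorption capacity ``AC_T``: ``AC_A`` corrected for uptake
  into micropores that are inaccessible to growth-factor-scale
  adsorbates.  The correction depends on the pore regime of the granule
  (macroporous / mixed / microporous), classified from the BJH micropore
  volume.

``AC_T`` is the clinically relevant quantity: it matches the volume of
bone-growth-factor preparation a fraction can adsorb.
"""

from __future__ import annotations

import enum
import math
import statistics
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .errors import ValidationError

__all__ = [
    "PoreRegime",
    "SampleMeasurement",
    "PorosimetryProfile",
    "PoreRegimeConfig",
    "IndicatorSet",
    "apparent_adsorption_capacity",
    "water_absorption_pct",
    "classify_pore_regime",
    "true_adsorption_capacity",
    "capacity_gain_pct",
    "compute_indicators",
    "summarize_indicator_sets",
]


class PoreRegime(enum.Enum):
    """Pore-structure regime of a granule, by BJH micropore volume."""

    MACRO = "MACRO"   # micropores < 1 cm³/g: AC_T = AC_A
    MIXED = "MIXED"   # 1–10 cm³/g: partial micropore correction (×0.85 on W_mB)
    MICRO = "MICRO"   # > 10 cm³/g: W_mB uptake excluded entirely


@dataclass(frozen=True)
class SampleMeasurement:
    """One replicate's bench measurements for the adsorption indicators.

    Masses in grams, volumes in millilitres.  ``m2`` is weighed after both
    degassing stages with liquid retained in intergranular spaces; ``m3``
    after draining that liquid on a slide.
    """

    sample_id: str
    m1: float
    m2: float
    m3: float
    V1: float
    V2: float
    V3: float = 2.0

    def __post_init__(self) -> None:
        for name in ("m1", "m2", "m3", "V1", "V2", "V3"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise ValidationError(
                    f"{self.sample_id}: {name} must be a finite positive number, got {v!r}"
                )
        if self.m3 > self.m2:
            raise ValidationError(
                f"{self.sample_id}: m3 ({self.m3} g) > m2 ({self.m2} g); "
                "draining cannot add mass"
            )
        if self.m1 > self.m3:
            raise ValidationError(
                f"{self.sample_id}: m1 ({self.m1} g) > m3 ({self.m3} g); "
                "wet mass cannot be below dry mass"
            )
        if self.V1 > self.V3:
            raise ValidationError(
                f"{self.sample_id}: V1 ({self.V1} mL) > V3 ({self.V3} mL); "
                "recovered volume cannot exceed the initial volume"
            )
        if self.V2 > self.V1:
            raise ValidationError(
                f"{self.sample_id}: V2 ({self.V2} mL) > V1 ({self.V1} mL); "
                "the active stage cannot recover more than the passive stage left"
            )


@dataclass(frozen=True)
class PorosimetryProfile:
    """Scalar porosimetry / SEM observations that drive the AC_T regime.

    ``micropore_volume`` is the BJH micropore volume in cm³/g.  The two
    booleans are operator observations from SEM imaging.  A
    ``regime_override`` pins the regime irrespective of the thresholds —
    used when the classification was established independently of the
    micropore number.
    """

    micropore_volume: float
    macropores_present: bool = True
    through_pores_present: bool = True
    regime_override: Optional[PoreRegime] = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.micropore_volume) and self.micropore_volume >= 0):
            raise ValidationError(
                f"micropore_volume must be finite and >= 0, got {self.micropore_volume!r}"
            )


@dataclass(frozen=True)
class PoreRegimeConfig:
    """Thresholds (cm³/g) and micropore correction for regime handling.

    Both boundary values belong to the MIXED band (closed interval), per
    the inclusive reading of the 1–10 cm³/g range.
    """

    lower_threshold: float = 1.0
    upper_threshold: float = 10.0
    micropore_correction: float = 0.85

    def __post_init__(self) -> None:
        if not (0 < self.lower_threshold < self.upper_threshold):
            raise ValidationError(
                "thresholds must satisfy 0 < lower < upper, got "
                f"{self.lower_threshold}, {self.upper_threshold}"
            )
        if not (0 < self.micropore_correction <= 1):
            raise ValidationError(
                f"micropore_correction must be in (0, 1], got {self.micropore_correction}"
            )


@dataclass(frozen=True)
class IndicatorSet:
    """Derived indicators for one replicate (or a replicate mean)."""

    sample_id: str
    AC_A: float          # apparent adsorption capacity, mL
    W_mA: float          # water absorption incl. intergranular spaces, %
    W_mB: float          # water absorption excl. intergranular spaces, %
    regime: PoreRegime
    AC_T: float          # true adsorption capacity, mL
    gain_pct: float      # AC_A / V3 × 100, unrounded
    gain_pct_rounded: int = field(default=0)

    def rounded(self) -> dict:
        """Report-precision view: volumes to 3 decimals, percents to 2."""
        return {
            "sample_id": self.sample_id,
            "AC_A": round(self.AC_A, 3),
            "W_mA": round(self.W_mA, 2),
            "W_mB": round(self.W_mB, 2),
            "regime": self.regime.value,
            "AC_T": round(self.AC_T, 3),
            "gain_pct": round(self.gain_pct, 2),
            "gain_pct_rounded": self.gain_pct_rounded,
        }


def apparent_adsorption_capacity(V1: float, V2: float, V3: float) -> float:
    """Liquid volume (mL) adsorbed over both degassing stages.

    Computed as the printed two-term sum ``(V3 - V1) + (V1 - V2)``; the
    telescoping identity makes this equal ``V3 - V2``.
    """
    if V2 <= 0:
        raise ValidationError(f"V2 must be positive, got {V2}")
    if V1 > V3:
        raise ValidationError(f"V1 ({V1} mL) exceeds V3 ({V3} mL)")
    if V2 > V1:
        raise ValidationError(f"V2 ({V2} mL) exceeds V1 ({V1} mL)")
    return (V3 - V1) + (V1 - V2)


def water_absorption_pct(m_wet: float, m1: float) -> float:
    """Water absorption by mass, % of dry mass.

    Pass ``m2`` for W_mA (intergranular liquid included), ``m3`` for W_mB
    (intergranular liquid drained).
    """
    if m1 <= 0:
        raise ValidationError(f"dry mass m1 must be positive, got {m1}")
    if m_wet < m1:
        raise ValidationError(
            f"wet mass ({m_wet} g) below dry mass ({m1} g): "
            "evaporation or weighing fault"
        )
    return (m_wet - m1) / m1 * 100.0


def classify_pore_regime(
    profile: PorosimetryProfile,
    cfg: PoreRegimeConfig | None = None,
) -> PoreRegime:
    """Assign the AC_T regime from the micropore volume (or an override)."""
    cfg = cfg or PoreRegimeConfig()
    if profile.regime_override is not None:
        return profile.regime_override
    v = profile.micropore_volume
    if v < cfg.lower_threshold:
        return PoreRegime.MACRO
    if v <= cfg.upper_threshold:
        return PoreRegime.MIXED
    return PoreRegime.MICRO


def true_adsorption_capacity(
    AC_A: float,
    W_mA: float,
    W_mB: float,
    regime: PoreRegime,
    cfg: PoreRegimeConfig | None = None,
) -> float:
    """Apparent capacity corrected for micropore uptake, mL.

    MACRO granules adsorb only through macropores, so AC_T = AC_A.
    MIXED granules retain 85 % of the drained-state uptake W_mB
    (the macropore share); MICRO granules' W_mB uptake is excluded
    entirely.  Always in [0, AC_A].
    """
    cfg = cfg or PoreRegimeConfig()
    if AC_A < 0:
        raise ValidationError(f"AC_A must be >= 0, got {AC_A}")
    if W_mA <= 0:
        raise ValidationError(f"W_mA must be positive, got {W_mA}")
    if W_mB < 0 or W_mB > W_mA:
        raise ValidationError(
            f"W_mB ({W_mB} %) must lie in [0, W_mA={W_mA} %]: "
            "inconsistent draining measurement"
        )
    if regime is PoreRegime.MACRO:
        return AC_A
    if regime is PoreRegime.MIXED:
        return AC_A * ((W_mA - W_mB) + W_mB * cfg.micropore_correction) / W_mA
    return AC_A * (W_mA - W_mB) / W_mA


def capacity_gain_pct(AC_A: float, V3: float) -> tuple[float, int]:
    """Adsorption-capacity gain from degassing, % of the initial volume.

    Returns ``(raw, nearest_integer)``; e.g. AC_A = 0.56 mL over
    V3 = 2.0 mL is a 28 % gain.
    """
    if V3 <= 0:
        raise ValidationError(f"V3 must be positive, got {V3}")
    if AC_A < 0 or AC_A > V3:
        raise ValidationError(f"AC_A ({AC_A} mL) must lie in [0, V3={V3} mL]")
    raw = 100.0 * AC_A / V3
    return raw, round(raw)


def compute_indicators(
    meas: SampleMeasurement,
    profile: PorosimetryProfile,
    cfg: PoreRegimeConfig | None = None,
) -> IndicatorSet:
    """Full indicator pipeline for one replicate measurement."""
    cfg = cfg or PoreRegimeConfig()
    ac_a = apparent_adsorption_capacity(meas.V1, meas.V2, meas.V3)
    w_ma = water_absorption_pct(meas.m2, meas.m1)
    w_mb = water_absorption_pct(meas.m3, meas.m1)
    regime = classify_pore_regime(profile, cfg)
    ac_t = true_adsorption_capacity(ac_a, w_ma, w_mb, regime, cfg)
    gain, gain_r = capacity_gain_pct(ac_a, meas.V3)
    return IndicatorSet(
        sample_id=meas.sample_id,
        AC_A=ac_a,
        W_mA=w_ma,
        W_mB=w_mb,
        regime=regime,
        AC_T=ac_t,
        gain_pct=gain,
        gain_pct_rounded=gain_r,
    )


def summarize_indicator_sets(sets: Sequence[IndicatorSet]) -> dict:
    """Mean ± sample SD (n−1 denominator) over replicates, per indicator.

    Mirrors the M±SD convention of replicate tables.  With a single
    replicate the SD is reported as None.
    """
    if not sets:
        raise ValidationError("no replicates to summarize")
    ids = {s.sample_id for s in sets}
    if len(ids) != 1:
        raise ValidationError(f"mixed sample_ids in one summary: {sorted(ids)}")
    regimes = {s.regime for s in sets}
    if len(regimes) != 1:
        raise ValidationError("replicates disagree on pore regime")
    n = len(sets)

    def ms(values):
        mean = statistics.fmean(values)
        sd = statistics.stdev(values) if n > 1 else None
        return {"mean": mean, "sd": sd}

    out = {
        "sample_id": sets[0].sample_id,
        "regime": sets[0].regime.value,
        "n": n,
    }
    for name in ("AC_A", "W_mA", "W_mB", "AC_T", "gain_pct"):
        out[name] = ms([getattr(s, name) for s in sets])
    out["gain_pct_rounded"] = round(out["gain_pct"]["mean"])
    return out
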