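"""Compaction coefficient of a granular bone-graft fraction.

A dry granular fraction is poured into a container (column height ``h1``),
then vibrated to its densest packing (height ``h2``).  The chain of
derived quantities — bed volume, bulk density, water adsorption by mass
and by volume, and their ratio ``d`` before and after compaction — yields
the compaction coefficient ``C_C = d_max / d``.  Algebraically ``C_C``
reduces to the tapped-to-bulk density ratio (a Hausner-style ratio) and
to ``h1 / h2``; the full chain is computed literally so the raw
intermediate quantities remain reportable.

Note on geometry: the bed-volume formula is ``V = (π r² h) / 4``, which
describes a cylinder only if ``r`` is the bore diameter; the field is
kept as ``r`` to match the bench sheet convention.  The geometric factor
cancels in ``C_C``, which is therefore insensitive to ``r`` entirely.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass
from typing import Sequence

from .errors import ValidationError

__all__ = [
    "CompactionMeasurement",
    "CompactionDerived",
    "derive_compaction_quantities",
    "compaction_coefficient",
    "summarize_compaction",
]


@dataclass(frozen=True)
class CompactionMeasurement:
    """One replicate of the compaction bench protocol.

    Masses in grams, heights and bore in centimetres.  ``m4`` is the mass
    saturated with saline in natural packing; ``m5`` after the degassing
    stages.
    """

    sample_id: str
    m1: float
    m4: float
    m5: float
    h1: float
    h2: float
    r: float = 1.0

    def __post_init__(self) -> None:
        for name in ("m1", "m4", "m5", "h1", "h2", "r"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise ValidationError(
                    f"{self.sample_id}: {name} must be a finite positive number, got {v!r}"
                )
        if self.h2 > self.h1:
            raise ValidationError(
                f"{self.sample_id}: h2 ({self.h2} cm) > h1 ({self.h1} cm); "
                "vibration cannot expand the bed"
            )
        if self.m4 < self.m1 or self.m5 < self.m1:
            raise ValidationError(
                f"{self.sample_id}: saturated masses (m4={self.m4}, m5={self.m5}) "
                f"cannot be below the dry mass m1={self.m1}"
            )


@dataclass(frozen=True)
class CompactionDerived:
    """Every intermediate of the compaction chain, plus C_C itself."""

    sample_id: str
    V_E: float      # bed volume, natural form, cm³
    rho_e: float    # bulk density, g/cm³
    W_mE: float     # water adsorption by mass, natural form, %
    W_vE: float     # water adsorption by volume, natural form, %
    d: float        # dependency coefficient W_vE / W_mE (= rho_e)
    V_C: float      # bed volume after compaction, cm³
    W_mC: float     # water adsorption by mass after compaction, %
    W_vC: float     # water adsorption by volume after compaction, %
    d_max: float    # dependency coefficient after compaction (= rho_c)
    rho_c: float    # tapped density, g/cm³
    C_C: float      # compaction coefficient d_max / d


def derive_compaction_quantities(meas: CompactionMeasurement) -> CompactionDerived:
    """Evaluate the full compaction chain for one replicate.

    Zero uptake (m4 = m1) is rejected: the dependency coefficient ``d``
    would be 0/0, and silently falling back to the reduced h-ratio would
    let the literal chain and the reduced form disagree.
    """
    if meas.m4 == meas.m1:
        raise ValidationError(
            f"{meas.sample_id}: zero uptake (m4 = m1 = {meas.m1} g) leaves the "
            "dependency coefficient d undefined (0/0)"
        )
    if meas.m5 == meas.m1:
        raise ValidationError(
            f"{meas.sample_id}: zero uptake (m5 = m1 = {meas.m1} g) leaves d_max "
            "undefined (0/0)"
        )
    V_E = (math.pi * meas.r**2 * meas.h1) / 4.0
    rho_e = meas.m1 / V_E
    W_mE = (meas.m4 - meas.m1) / meas.m1 * 100.0
    W_vE = (meas.m4 - meas.m1) / V_E * 100.0
    d = W_vE / W_mE
    V_C = (math.pi * meas.r**2 * meas.h2) / 4.0
    W_mC = (meas.m5 - meas.m1) / meas.m1 * 100.0
    W_vC = (meas.m5 - meas.m1) / V_C * 100.0
    d_max = W_vC / W_mC
    rho_c = meas.m1 / V_C
    return CompactionDerived(
        sample_id=meas.sample_id,
        V_E=V_E, rho_e=rho_e, W_mE=W_mE, W_vE=W_vE, d=d,
        V_C=V_C, W_mC=W_mC, W_vC=W_vC, d_max=d_max, rho_c=rho_c,
        C_C=d_max / d,
    )


def compaction_coefficient(derived: CompactionDerived) -> float:
    """C_C = d_max / d, the tapped-to-bulk density (Hausner-style) ratio."""
    if derived.d <= 0:
        raise ValidationError(f"dependency coefficient d must be positive, got {derived.d}")
    return derived.d_max / derived.d


def summarize_compaction(derived: Sequence[CompactionDerived]) -> dict:
    """Mean ± sample SD of C_C over replicates of one sample."""
    if not derived:
        raise ValidationError("no replicates to summarize")
    ids = {dd.sample_id for dd in derived}
    if len(ids) != 1:
        raise ValidationError(f"mixed sample_ids in one summary: {sorted(ids)}")
    vals = [dd.C_C for dd in derived]
    n = len(vals)
    return {
        "sample_id": derived[0].sample_id,
        "n": n,
        "C_C": {
            "mean": statistics.fmean(vals),
            "sd": statistics.stdev(vals) if n > 1 else None,
        },
    }
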