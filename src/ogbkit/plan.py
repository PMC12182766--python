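"""Surgical-planning arithmetic built on the prognostic indicators.

Interpretive layer: the compaction coefficient is read as a multiplier on
the dry fraction volume ordered for a defect (the bed will compact by
C_C in situ, so C_C × defect volume of dry fraction is required), and the
true adsorption capacity per millilitre of dry fraction sets the volume
of bone-growth-factor (BGF) preparation that volume can adsorb.
"""

from __future__ import annotations

from .errors import ValidationError

__all__ = ["plan_graft"]


def plan_graft(
    defect_volume: float, C_C: float, AC_T_per_mL: float
) -> tuple[float, float]:
    """Dry-fraction and BGF volumes (mL) to order for a defect.

    Returns ``(dry_volume, bgf_volume)`` with
    ``dry_volume = defect_volume × C_C`` and
    ``bgf_volume = dry_volume × AC_T_per_mL``.
    """
    if defect_volume <= 0:
        raise ValidationError(f"defect_volume must be positive, got {defect_volume}")
    if C_C < 1:
        raise ValidationError(f"C_C must be >= 1, got {C_C}")
    if AC_T_per_mL < 0:
        raise ValidationError(f"AC_T_per_mL must be >= 0, got {AC_T_per_mL}")
    dry = defect_volume * C_C
    return dry, dry * AC_T_per_mL
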