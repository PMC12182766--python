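"""CSV sheet readers/writers and the JSON analysis report.

Three sheet schemas are recognized by header, one row per replicate:

* adsorption indicators —
  ``sample_id,replicate,m1_g,m2_g,m3_g,V1_mL,V2_mL,V3_mL,
  micropore_cm3_per_g,macropores,through_pores,regime_override``
* compaction — ``sample_id,replicate,m1_g,m4_g,m5_g,h1_cm,h2_cm,r_cm``
* degassing kinetics — ``sample_id,replicate,t_min,pct_initial_volume``

Validation is strict by default; in lenient mode rows violating physical
invariants are logged as warnings and skipped (bench sheets do contain
entry errors), and the skipped line numbers are retained in the result.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .compaction import CompactionMeasurement, derive_compaction_quantities, summarize_compaction
from .errors import FormatError, ValidationError
from .indicators import (
    IndicatorSet,
    PoreRegime,
    PoreRegimeConfig,
    PorosimetryProfile,
    SampleMeasurement,
    compute_indicators,
    summarize_indicator_sets,
)
from .kinetics import DegassingSeries, LogisticModel, summarize_replicates

logger = logging.getLogger("ogbkit")

INDICATOR_COLUMNS = [
    "sample_id", "replicate", "m1_g", "m2_g", "m3_g",
    "V1_mL", "V2_mL", "V3_mL",
    "micropore_cm3_per_g", "macropores", "through_pores", "regime_override",
]
COMPACTION_COLUMNS = [
    "sample_id", "replicate", "m1_g", "m4_g", "m5_g", "h1_cm", "h2_cm", "r_cm",
]
KINETICS_COLUMNS = ["sample_id", "replicate", "t_min", "pct_initial_volume"]

_TRUE = {"true", "1", "yes", "y"}
_FALSE = {"false", "0", "no", "n", ""}


def _parse_bool(value, line: int, column: str) -> bool:
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE or s == "nan":
        return False
    raise ValidationError(f"line {line}: {column} must be boolean-like, got {value!r}")


@dataclass
class SheetResult:
    """Validated records plus row-level problems (line numbers are 1-based
    file lines, header = line 1)."""

    kind: str                    # "indicators" | "compaction" | "kinetics"
    records: list
    profiles: dict               # sample_id -> PorosimetryProfile (indicators only)
    skipped: list                # (line, message) pairs downgraded in lenient mode


def detect_schema(columns) -> str:
    cols = list(columns)
    if cols == INDICATOR_COLUMNS:
        return "indicators"
    if cols == COMPACTION_COLUMNS:
        return "compaction"
    if cols == KINETICS_COLUMNS:
        return "kinetics"
    raise FormatError(
        f"unrecognized sheet header {cols!r}; expected one of the "
        "indicators / compaction / kinetics schemas"
    )


def read_measurement_sheet(path: str | Path, lenient: bool = False) -> SheetResult:
    """Read and validate a measurement sheet, dispatching on its header."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    kind = detect_schema(df.columns)

    records, profiles, skipped = [], {}, []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            if kind == "indicators":
                rec = SampleMeasurement(
                    sample_id=row["sample_id"],
                    m1=float(row["m1_g"]),
                    m2=float(row["m2_g"]),
                    m3=float(row["m3_g"]),
                    V1=float(row["V1_mL"]),
                    V2=float(row["V2_mL"]),
                    V3=float(row["V3_mL"]),
                )
                override = row["regime_override"].strip()
                profiles[rec.sample_id] = PorosimetryProfile(
                    micropore_volume=float(row["micropore_cm3_per_g"]),
                    macropores_present=_parse_bool(row["macropores"], line, "macropores"),
                    through_pores_present=_parse_bool(
                        row["through_pores"], line, "through_pores"
                    ),
                    regime_override=PoreRegime(override) if override else None,
                )
            elif kind == "compaction":
                rec = CompactionMeasurement(
                    sample_id=row["sample_id"],
                    m1=float(row["m1_g"]),
                    m4=float(row["m4_g"]),
                    m5=float(row["m5_g"]),
                    h1=float(row["h1_cm"]),
                    h2=float(row["h2_cm"]),
                    r=float(row["r_cm"]),
                )
            else:
                rec = (
                    row["sample_id"],
                    int(row["replicate"]),
                    float(row["t_min"]),
                    float(row["pct_initial_volume"]),
                )
        except (ValidationError, ValueError) as exc:
            msg = f"line {line}: {exc}"
            if lenient and isinstance(exc, ValidationError):
                logger.warning("lenient mode, skipping row — %s", msg)
                skipped.append((line, str(exc)))
                continue
            raise ValidationError(msg) from exc
        records.append(rec)

    if kind == "kinetics":
        by_sample: dict[str, list] = {}
        for sid, rep, t, pct in records:
            by_sample.setdefault(sid, []).append((t, pct, rep))
        records = [
            DegassingSeries(sample_id=sid, points=tuple(pts))
            for sid, pts in by_sample.items()
        ]
    return SheetResult(kind=kind, records=records, profiles=profiles, skipped=skipped)


def write_indicator_sheet(records, profiles, path: str | Path) -> None:
    """Write SampleMeasurement records (+ porosimetry) back to the CSV schema."""
    rows = []
    reps: dict[str, int] = {}
    for rec in records:
        reps[rec.sample_id] = reps.get(rec.sample_id, 0) + 1
        prof = profiles[rec.sample_id]
        rows.append({
            "sample_id": rec.sample_id,
            "replicate": reps[rec.sample_id],
            "m1_g": repr(float(rec.m1)), "m2_g": repr(float(rec.m2)), "m3_g": repr(float(rec.m3)),
            "V1_mL": repr(float(rec.V1)), "V2_mL": repr(float(rec.V2)), "V3_mL": repr(float(rec.V3)),
            "micropore_cm3_per_g": repr(float(prof.micropore_volume)),
            "macropores": str(prof.macropores_present).lower(),
            "through_pores": str(prof.through_pores_present).lower(),
            "regime_override": prof.regime_override.value if prof.regime_override else "",
        })
    pd.DataFrame(rows, columns=INDICATOR_COLUMNS).to_csv(path, index=False)


def write_compaction_sheet(records, path: str | Path) -> None:
    rows = []
    reps: dict[str, int] = {}
    for rec in records:
        reps[rec.sample_id] = reps.get(rec.sample_id, 0) + 1
        rows.append({
            "sample_id": rec.sample_id, "replicate": reps[rec.sample_id],
            "m1_g": repr(float(rec.m1)), "m4_g": repr(float(rec.m4)), "m5_g": repr(float(rec.m5)),
            "h1_cm": repr(float(rec.h1)), "h2_cm": repr(float(rec.h2)), "r_cm": repr(float(rec.r)),
        })
    pd.DataFrame(rows, columns=COMPACTION_COLUMNS).to_csv(path, index=False)


def write_kinetics_sheet(series_list, path: str | Path) -> None:
    rows = [
        {"sample_id": s.sample_id, "replicate": rep, "t_min": repr(float(t)),
         "pct_initial_volume": repr(float(pct))}
        for s in series_list
        for (t, pct, rep) in s.points
    ]
    pd.DataFrame(rows, columns=KINETICS_COLUMNS).to_csv(path, index=False)


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def provenance_block(input_path=None, config=None, seed=None) -> dict:
    block = {"tool": "ogbkit", "version": __version__}
    if input_path is not None:
        block["input"] = {
            "path": str(input_path),
            "sha256": file_sha256(input_path),
        }
    if config is not None:
        block["config"] = config
    if seed is not None:
        block["seed"] = seed
    return block


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, PoreRegime):
        return obj.value
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def indicators_report(sheet: SheetResult, cfg: PoreRegimeConfig,
                      input_path=None) -> dict:
    """Per-replicate indicator sets plus M±SD summaries, keyed by sample."""
    if sheet.kind != "indicators":
        raise FormatError(f"expected an indicators sheet, got {sheet.kind}")
    by_sample: dict[str, list[IndicatorSet]] = {}
    for rec in sheet.records:
        ind = compute_indicators(rec, sheet.profiles[rec.sample_id], cfg)
        by_sample.setdefault(rec.sample_id, []).append(ind)
    report = {
        "samples": {
            sid: {
                "replicates": [_jsonable(s) for s in sets],
                "replicates_rounded": [s.rounded() for s in sets],
                "summary": _jsonable(summarize_indicator_sets(sets)),
            }
            for sid, sets in by_sample.items()
        },
        "skipped_rows": sheet.skipped,
        "provenance": provenance_block(input_path, config=_jsonable(cfg)),
    }
    return report


def compaction_report(sheet: SheetResult, input_path=None) -> dict:
    if sheet.kind != "compaction":
        raise FormatError(f"expected a compaction sheet, got {sheet.kind}")
    by_sample: dict[str, list] = {}
    for rec in sheet.records:
        by_sample.setdefault(rec.sample_id, []).append(derive_compaction_quantities(rec))
    return {
        "samples": {
            sid: {
                "replicates": [_jsonable(d) for d in ds],
                "summary": summarize_compaction(ds),
            }
            for sid, ds in by_sample.items()
        },
        "skipped_rows": sheet.skipped,
        "provenance": provenance_block(input_path),
    }


def kinetics_report(series: DegassingSeries, model: LogisticModel,
                    input_path=None, config=None) -> dict:
    return {
        "sample_id": series.sample_id,
        "model": _jsonable(model),
        "replicate_summary": [_jsonable(s) for s in summarize_replicates(series)],
        "n_points": len(series.points),
        "provenance": provenance_block(input_path, config=config),
    }


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=False) + "\n")
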