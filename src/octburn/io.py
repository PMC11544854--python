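"""Cohort tables, volume files, reports and run configuration.

The cohort table is a UTF-8 comma-delimited file with a mandatory header:

    wound_id,patient_id,skin_type,surf1,epi1,dermal1,vasc1,
    surf2,epi2,dermal2,vasc2,clinical_judgment,outcome,days_to_graft

Empty strings mean absent (the observer-2 block, clinical_judgment and
days_to_graft may be empty). Volumes travel as one multi-page TIFF per
channel; statistics reports as flat key=value text.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .cohort import ClinicalJudgment, Outcome, WoundRecord
from .errors import CohortValidationError, ConfigError, GradingError
from .phantom import GraderConfig, OCTVolume, PhantomSpec
from .score import ITEM_NAMES, FeatureGrades, SkinType, validate_grades

__all__ = [
    "COHORT_COLUMNS",
    "read_cohort",
    "write_cohort",
    "read_volume",
    "write_volume",
    "write_report",
    "RunConfig",
    "load_run_config",
]

log = logging.getLogger("octburn")

COHORT_COLUMNS: tuple[str, ...] = (
    "wound_id", "patient_id", "skin_type",
    "surf1", "epi1", "dermal1", "vasc1",
    "surf2", "epi2", "dermal2", "vasc2",
    "clinical_judgment", "outcome", "days_to_graft",
)

_OBS_COLS = {"1": ("surf1", "epi1", "dermal1", "vasc1"),
             "2": ("surf2", "epi2", "dermal2", "vasc2")}


def _parse_int(value: object, row: int, column: str) -> Optional[int]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    text = str(value).strip()
    if text == "":
        return None
    try:
        return int(text)
    except ValueError:
        raise CohortValidationError(
            f"row {row}: column {column!r}: malformed integer {text!r}"
        ) from None


def _row_grades(row_values: dict, row_num: int, obs: str,
                skin_type: SkinType) -> Optional[FeatureGrades]:
    cols = _OBS_COLS[obs]
    values = [_parse_int(row_values[c], row_num, c) for c in cols]
    if all(v is None for v in values):
        return None
    missing = [c for c, v in zip(cols, values) if v is None]
    if missing:
        raise CohortValidationError(
            f"row {row_num}: incomplete observer-{obs} grading: "
            f"missing {', '.join(missing)}"
        )
    raw = dict(zip(ITEM_NAMES, values))
    try:
        return validate_grades(raw, skin_type)  # type: ignore[arg-type]
    except GradingError as exc:
        raise CohortValidationError(f"row {row_num}: {exc}") from exc


def _parse_row(row_values: dict, row_num: int) -> WoundRecord:
    try:
        skin = SkinType(str(row_values["skin_type"]).strip())
    except ValueError:
        raise CohortValidationError(
            f"row {row_num}: column 'skin_type': unknown value "
            f"{row_values['skin_type']!r} (allowed: glabrous, hair_bearing)"
        ) from None
    grades1 = _row_grades(row_values, row_num, "1", skin)
    if grades1 is None:
        raise CohortValidationError(
            f"row {row_num}: observer-1 grades are mandatory"
        )
    grades2 = _row_grades(row_values, row_num, "2", skin)
    judgment_raw = str(row_values.get("clinical_judgment") or "").strip()
    judgment = None
    if judgment_raw and judgment_raw.lower() != "nan":
        try:
            judgment = ClinicalJudgment(judgment_raw)
        except ValueError:
            raise CohortValidationError(
                f"row {row_num}: column 'clinical_judgment': unknown value "
                f"{judgment_raw!r}"
            ) from None
    outcome_raw = str(row_values.get("outcome") or "").strip()
    try:
        outcome = Outcome(outcome_raw)
    except ValueError:
        raise CohortValidationError(
            f"row {row_num}: column 'outcome': unknown value {outcome_raw!r}"
        ) from None
    days = _parse_int(row_values.get("days_to_graft"), row_num,
                      "days_to_graft")
    try:
        return WoundRecord(
            wound_id=str(row_values["wound_id"]).strip(),
            patient_id=str(row_values["patient_id"]).strip(),
            skin_type=skin,
            grades_obs1=grades1,
            grades_obs2=grades2,
            clinical_judgment=judgment,
            outcome=outcome,
            days_to_graft=days,
        )
    except CohortValidationError as exc:
        raise CohortValidationError(f"row {row_num}: {exc}") from exc


def read_cohort(path: str | Path, strict: bool = True
                ) -> tuple[list[WoundRecord], list[str]]:
    """Read and validate a cohort table.

    In strict mode the first invalid row aborts; in permissive mode
    invalid rows are skipped and their row-numbered messages returned
    (mirroring the exclusion of unusable images from the study cohort).

    Returns (records, skipped_messages).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError(
            f"cohort table missing column(s): {', '.join(missing)}"
        )
    dupes = df["wound_id"][df["wound_id"].duplicated()].unique()
    if len(dupes):
        raise CohortValidationError(
            f"duplicate wound_id(s): {', '.join(map(str, dupes))}"
        )
    records: list[WoundRecord] = []
    skipped: list[str] = []
    for pos, (_, row) in enumerate(df.iterrows()):
        row_num = pos + 2  # 1-based, after the header line
        try:
            records.append(_parse_row(row.to_dict(), row_num))
        except CohortValidationError as exc:
            if strict:
                raise
            skipped.append(str(exc))
    if skipped:
        log.warning("read_cohort: skipped %d invalid row(s)", len(skipped))
    return records, skipped


def _grades_cells(grades: Optional[FeatureGrades]) -> list[str]:
    if grades is None:
        return ["", "", "", ""]
    return [str(getattr(grades, item)) for item in ITEM_NAMES]


def write_cohort(records: Sequence[WoundRecord], path: str | Path) -> None:
    """Write records to the cohort CSV schema (empty string = absent)."""
    rows = []
    for r in records:
        rows.append([
            r.wound_id, r.patient_id, r.skin_type.value,
            *_grades_cells(r.grades_obs1), *_grades_cells(r.grades_obs2),
            r.clinical_judgment.value if r.clinical_judgment else "",
            r.outcome.value,
            "" if r.days_to_graft is None else str(r.days_to_graft),
        ])
    df = pd.DataFrame(rows, columns=list(COHORT_COLUMNS))
    df.to_csv(path, index=False, lineterminator="\n")


def write_volume(volume: OCTVolume, prefix: str | Path) -> dict[str, Path]:
    """Write a volume as `<prefix>_structural.tif` / `<prefix>_vascular.tif`.

    Channels are stored as 16-bit multi-page TIFF (one page per depth);
    a JSON sidecar records the voxel geometry.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in ("structural", "vascular"):
        arr = getattr(volume, name)
        data = np.clip(arr * 65535.0, 0, 65535).astype(np.uint16)
        p = prefix.with_name(prefix.name + f"_{name}.tif")
        tifffile.imwrite(p, data)
        paths[name] = p
    meta_path = prefix.with_name(prefix.name + "_meta.json")
    meta_path.write_text(json.dumps({"voxel_um": list(volume.voxel_um)}))
    paths["meta"] = meta_path
    return paths


def read_volume(prefix: str | Path) -> OCTVolume:
    """Read a volume written by :func:`write_volume`."""
    prefix = Path(prefix)
    channels = {}
    for name in ("structural", "vascular"):
        p = prefix.with_name(prefix.name + f"_{name}.tif")
        if not p.exists():
            raise ConfigError(f"volume channel file not found: {p}")
        channels[name] = tifffile.imread(p).astype(np.float32) / 65535.0
    meta_path = prefix.with_name(prefix.name + "_meta.json")
    voxel = (8.0, 24.0, 24.0)
    if meta_path.exists():
        voxel = tuple(json.loads(meta_path.read_text())["voxel_um"])
    return OCTVolume(structural=channels["structural"],
                     vascular=channels["vascular"],
                     voxel_um=voxel)  # type: ignore[arg-type]


def write_report(entries: dict[str, object], path: str | Path) -> None:
    """Flat key=value report; nested mappings are dotted-flattened."""
    lines: list[str] = []

    def emit(prefix: str, value: object) -> None:
        if isinstance(value, dict):
            for k, v in value.items():
                emit(f"{prefix}.{k}" if prefix else str(k), v)
        else:
            lines.append(f"{prefix}={value}")

    emit("", entries)
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


_RUN_CONFIG_KEYS = {
    "threshold", "ci_method", "rounding_decimals", "deep_outcome_rule",
    "observer", "grader", "phantom", "cohort", "seed",
}


@dataclass(frozen=True)
class RunConfig:
    """Resolved run configuration for the CLI pipeline."""

    threshold: int = 4
    ci_method: str = "wilson"
    rounding_decimals: int = 0
    deep_outcome_rule: str = "grafted_or_refused"
    observer: str = "obs1"
    seed: int = 0
    grader: Optional[GraderConfig] = None
    phantom: Optional[dict] = None
    cohort: Optional[dict] = None


def load_run_config(path: Optional[str | Path]) -> RunConfig:
    """Load a YAML run configuration; unknown keys are rejected."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise ConfigError("run config must be a mapping")
    unknown = set(raw) - _RUN_CONFIG_KEYS
    if unknown:
        raise ConfigError(
            f"unknown run-config key(s): {', '.join(sorted(unknown))}"
        )
    grader = None
    if "grader" in raw:
        g = raw.pop("grader")
        valid = {f.name for f in GraderConfig.__dataclass_fields__.values()}
        bad = set(g) - valid
        if bad:
            raise ConfigError(
                f"unknown grader key(s): {', '.join(sorted(bad))}"
            )
        g = {k: tuple(v) if isinstance(v, list) else v for k, v in g.items()}
        grader = GraderConfig(**g)
    cfg = RunConfig(grader=grader, **raw)
    log.info("resolved run config: %s", cfg)
    return cfg


def phantom_spec_from_mapping(raw: dict) -> PhantomSpec:
    """Build a PhantomSpec from a plain mapping (e.g. parsed YAML)."""
    raw = dict(raw)
    if "skin_type" in raw:
        raw["skin_type"] = SkinType(raw["skin_type"])
    for key in ("field_of_view_mm", "voxel_um"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    valid = {f.name for f in PhantomSpec.__dataclass_fields__.values()}
    bad = set(raw) - valid
    if bad:
        raise ConfigError(
            f"unknown phantom-spec key(s): {', '.join(sorted(bad))}"
        )
    return PhantomSpec(**raw).validate()
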