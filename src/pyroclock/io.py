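"""Readers and writers for sample tables, clock configs and reports.

All formats are plain text (CSV / YAML) so outputs are directly consumable
from R or a spreadsheet:

* sample table — CSV with header ``sample_id,sex,age,<site_id>,...``;
* clock config — YAML, ``models: [{id, intercept, terms: [{site, coef, power}]}]``;
* accuracy report — long-format CSV ``model,age_group,sex,metric,threshold,value,n``.
"""

from __future__ import annotations

import csv
import math
from typing import Optional, Sequence

import pandas as pd
import yaml

from .datamodel import (
    AccuracyReport,
    ClockModel,
    ClockTerm,
    CpGSite,
    FormatError,
    MAX_VALID_AGE,
    PredictionRecord,
    Sample,
    Sex,
    ValidationError,
    parse_sex,
)

__all__ = [
    "read_samples",
    "write_samples",
    "read_clock_config",
    "write_report",
    "read_report",
    "write_predictions",
    "read_predictions",
]

_REQUIRED_COLUMNS = ("sample_id", "sex", "age")


def _resolve_site_columns(
    columns: Sequence[str], panel: Optional[Sequence[CpGSite]]
) -> dict[str, str]:
    """Map CSV column name -> canonical site_id.

    With a panel, alias spellings (e.g. "ELOVL26") resolve to the canonical
    GENE_ordinal id; without one, every non-required column is taken as a
    site verbatim.
    """
    extra = [c for c in columns if c not in _REQUIRED_COLUMNS]
    if panel is None:
        return {c: c for c in extra}
    mapping = {}
    for c in extra:
        for site in panel:
            if site.matches(c):
                mapping[c] = site.site_id
                break
    return mapping


def read_samples(path, panel: Optional[Sequence[CpGSite]] = None) -> list[Sample]:
    """Read and validate a sample CSV.

    Every malformed cell is reported with its file row number; a single
    :class:`ValidationError` (or :class:`FormatError` for structural
    problems) lists all of them — rows are never silently dropped.
    Empty methylation cells mark the site as missing for that sample.
    """
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file, header row required")
        missing = [c for c in _REQUIRED_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise FormatError(f"{path}: missing required column(s) {missing}")
        site_cols = _resolve_site_columns(reader.fieldnames, panel)
        if panel is not None:
            found = set(site_cols.values())
            absent = [s.site_id for s in panel if s.site_id not in found]
            if absent:
                raise FormatError(f"{path}: no column for panel site(s) {absent}")

        samples: list[Sample] = []
        errors: list[str] = []
        for lineno, row in enumerate(reader, start=2):
            row_errors = []
            sample_id = (row.get("sample_id") or "").strip()
            if not sample_id:
                row_errors.append("empty sample_id")
            try:
                age = float(row["age"])
                if not (0.0 <= age <= MAX_VALID_AGE) or not math.isfinite(age):
                    row_errors.append(f"age {row['age']} outside [0, {MAX_VALID_AGE:g}]")
            except (TypeError, ValueError):
                row_errors.append(f"non-numeric age {row.get('age')!r}")
                age = float("nan")
            meth: dict[str, float] = {}
            for col, sid in site_cols.items():
                cell = (row.get(col) or "").strip()
                if cell == "":
                    continue  # missing site, allowed
                try:
                    value = float(cell)
                except ValueError:
                    row_errors.append(f"non-numeric methylation {cell!r} at {sid}")
                    continue
                if not (math.isfinite(value) and 0.0 <= value <= 100.0):
                    row_errors.append(
                        f"sample {sample_id!r}: methylation {value:g} at {sid} "
                        "outside [0, 100]"
                    )
                else:
                    meth[sid] = value
            if row_errors:
                errors.extend(f"row {lineno}: {e}" for e in row_errors)
            else:
                samples.append(
                    Sample(
                        sample_id=sample_id,
                        sex=parse_sex(row.get("sex", "")),
                        age=age,
                        methylation=meth,
                    )
                )
    if errors:
        raise ValidationError(f"{path}: {len(errors)} invalid cell(s):\n" + "\n".join(errors))
    return samples


def write_samples(samples: Sequence[Sample], path) -> None:
    """Write a sample CSV at full float precision (lossless round-trip)."""
    if not samples:
        raise ValidationError("write_samples: no samples to write")
    site_ids = sorted({sid for s in samples for sid in s.methylation})
    sex_label = {Sex.FEMALE: "F", Sex.MALE: "M", Sex.UNKNOWN: "unknown"}
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow([*_REQUIRED_COLUMNS, *site_ids])
        for s in samples:
            writer.writerow(
                [
                    s.sample_id,
                    sex_label[s.sex],
                    repr(s.age),
                    *[
                        repr(s.methylation[sid]) if sid in s.methylation else ""
                        for sid in site_ids
                    ],
                ]
            )


def read_clock_config(path) -> list[ClockModel]:
    """Load clock model definitions from YAML.

    Rejects duplicate model ids, empty term lists and non-numeric
    coefficients; the optional per-model ``valid_age_range`` is [lo, hi]
    in years.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "models" not in raw:
        raise FormatError(f"{path}: expected a top-level 'models' list")
    models: list[ClockModel] = []
    seen: set[str] = set()
    for entry in raw["models"]:
        model_id = str(entry.get("id", ""))
        if model_id in seen:
            raise ValidationError(f"{path}: duplicate model id {model_id!r}")
        seen.add(model_id)
        try:
            intercept = float(entry["intercept"])
        except (KeyError, TypeError, ValueError):
            raise FormatError(
                f"{path}: model {model_id!r}: missing or non-numeric intercept"
            ) from None
        raw_terms = entry.get("terms") or []
        terms = []
        for t in raw_terms:
            try:
                coef = float(t["coef"])
            except (KeyError, TypeError, ValueError):
                raise FormatError(
                    f"{path}: model {model_id!r}: non-numeric coefficient in term {t!r}"
                ) from None
            terms.append(
                ClockTerm(
                    site_id=str(t["site"]),
                    coefficient=coef,
                    power=int(t.get("power", 1)),
                )
            )
        if not terms:
            raise ValidationError(f"{path}: model {model_id!r} has no terms")
        rng = entry.get("valid_age_range")
        models.append(
            ClockModel(
                model_id=model_id,
                intercept=intercept,
                terms=tuple(terms),
                valid_age_range=tuple(float(v) for v in rng) if rng else None,
            )
        )
    return models


def write_report(reports: Sequence[AccuracyReport], path) -> None:
    """Write accuracy reports as long-format CSV, one row per metric value.

    PCP rows carry their threshold; r2/mad/see rows leave it blank.  Values
    are written at 6 significant digits (the round-trip guarantee).
    """
    if not reports:
        raise ValidationError("write_report: no reports to write")
    rows = []
    for rep in reports:
        base = dict(model=rep.model_id, age_group=rep.age_group, sex=rep.sex, n=rep.n)
        for name, value in (("r2", rep.r2), ("mad", rep.mad), ("see", rep.see)):
            if value is not None:
                rows.append({**base, "metric": name, "threshold": "", "value": f"{value:.6g}"})
        for thr in sorted(rep.pcp):
            rows.append(
                {**base, "metric": "pcp", "threshold": f"{thr:g}", "value": f"{rep.pcp[thr]:.6g}"}
            )
    pd.DataFrame(
        rows, columns=["model", "age_group", "sex", "metric", "threshold", "value", "n"]
    ).to_csv(path, index=False)


def read_report(path) -> pd.DataFrame:
    """Read a long-format report CSV back into a DataFrame."""
    df = pd.read_csv(path, dtype={"model": str, "age_group": str, "sex": str, "metric": str})
    expected = {"model", "age_group", "sex", "metric", "threshold", "value", "n"}
    if not expected.issubset(df.columns):
        raise FormatError(f"{path}: missing report columns {expected - set(df.columns)}")
    return df


_PREDICTION_COLUMNS = [
    "sample_id", "sex", "age", "model", "predicted_age", "delta_age", "age_group",
]


def write_predictions(records: Sequence[PredictionRecord], path) -> None:
    if not records:
        raise ValidationError("write_predictions: no records to write")
    sex_label = {Sex.FEMALE: "F", Sex.MALE: "M", Sex.UNKNOWN: "unknown"}
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_PREDICTION_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.sample_id,
                    sex_label[r.sex],
                    repr(r.age),
                    r.model_id,
                    repr(r.predicted_age),
                    repr(r.delta_age),
                    r.age_group,
                ]
            )


def read_predictions(path) -> list[PredictionRecord]:
    df = pd.read_csv(
        path,
        dtype={"sample_id": str, "model": str, "age_group": str},
        float_precision="round_trip",
    )
    missing = [c for c in _PREDICTION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing prediction column(s) {missing}")
    return [
        PredictionRecord.build(
            sample_id=row.sample_id,
            sex=parse_sex(row.sex),
            age=float(row.age),
            predicted_age=float(row.predicted_age),
            age_group=str(row.age_group),
            model_id=str(row.model),
        )
        for row in df.itertuples()
    ]
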