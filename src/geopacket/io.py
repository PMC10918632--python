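"""Reading and writing sample sheets, annotations, and reports.

Sample sheets are CSV or TSV with required headers ``sample``,
``latitude`` and ``longitude`` (case-insensitive); every other column is
carried through untouched.  The delimiter is inferred from the extension
(.csv → comma, .tsv/.txt → tab) and can be overridden.  Coordinates are
read as raw strings — parsing and QC happen downstream, so a malformed
field is preserved for the validation report instead of becoming NaN.
"""

from __future__ import annotations

import csv
import json
import os
from pathlib import Path

import pandas as pd

from .datapacket import LayerKind, LayerMeta
from .errors import InputError
from .query import AnnotationRecord, CategoricalValue, SampleRecord
from .validate import ValidationReport

_REQUIRED = ("sample", "latitude", "longitude")


def infer_delimiter(path: str | os.PathLike, override: str | None = None) -> str:
    if override:
        return override
    suffix = Path(path).suffix.lower()
    return "," if suffix == ".csv" else "\t"


def read_sheet(
    path: str | os.PathLike, delimiter: str | None = None
) -> list[SampleRecord]:
    """Read a sample sheet into records, all fields as submitted."""
    sep = infer_delimiter(path, delimiter)
    try:
        frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, encoding="utf-8")
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError, UnicodeDecodeError) as exc:
        raise InputError(f"cannot read sample sheet {path}: {exc}") from None
    lower = {c.lower(): c for c in frame.columns}
    missing = [name for name in _REQUIRED if name not in lower]
    if missing:
        raise InputError(
            f"sample sheet {path} lacks required column(s): {', '.join(missing)}"
        )
    extras_cols = [c for c in frame.columns if c.lower() not in _REQUIRED]
    records = []
    for _, row in frame.iterrows():
        records.append(
            SampleRecord(
                sample_id=row[lower["sample"]],
                latitude=row[lower["latitude"]],
                longitude=row[lower["longitude"]],
                extras={c: row[c] for c in extras_cols},
            )
        )
    return records


def write_sheet(records: list[SampleRecord], path: str | os.PathLike,
                delimiter: str | None = None) -> None:
    sep = infer_delimiter(path, delimiter)
    extras_cols: list[str] = []
    for rec in records:
        for c in rec.extras:
            if c not in extras_cols:
                extras_cols.append(c)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=sep)
        writer.writerow(["sample", "latitude", "longitude", *extras_cols])
        for rec in records:
            writer.writerow(
                [rec.sample_id, rec.latitude, rec.longitude,
                 *(rec.extras.get(c, "") for c in extras_cols)]
            )


def write_annotations(
    records: list[SampleRecord],
    annotations: list[AnnotationRecord],
    metas: list[LayerMeta],
    path: str | os.PathLike,
    delimiter: str | None = None,
) -> None:
    """Write the annotated sheet: original columns preserved, plus per
    feature a code+label column pair (categorical) or a value column
    (continuous), plus the per-record status."""
    sep = infer_delimiter(path, delimiter)
    extras_cols: list[str] = []
    for rec in records:
        for c in rec.extras:
            if c not in extras_cols:
                extras_cols.append(c)
    feat_cols: list[str] = []
    for meta in metas:
        if meta.kind is LayerKind.CATEGORICAL:
            feat_cols += [f"{meta.feature_name}_code", f"{meta.feature_name}_label"]
        else:
            feat_cols.append(meta.feature_name)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=sep)
        writer.writerow(["sample", "latitude", "longitude", *extras_cols, *feat_cols, "status"])
        for rec, ann in zip(records, annotations, strict=True):
            row = [rec.sample_id, rec.latitude, rec.longitude]
            row += [rec.extras.get(c, "") for c in extras_cols]
            for meta in metas:
                value = ann.values.get(meta.feature_name)
                if meta.kind is LayerKind.CATEGORICAL:
                    if isinstance(value, CategoricalValue):
                        row += [value.code, value.short_label]
                    else:
                        row += ["", ""]
                else:
                    row.append("" if value is None else repr(float(value)))
            row.append(ann.status.value)
            writer.writerow(row)


def write_validation_report(
    report: ValidationReport,
    csv_path: str | os.PathLike,
    summary_path: str | os.PathLike | None = None,
) -> None:
    """Per-record flags as CSV plus a JSON summary of dataset statistics."""
    with open(csv_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample", "flags"])
        for sid, flags in report.per_record.items():
            writer.writerow([sid, ";".join(sorted(f.value for f in flags))])
    if summary_path is not None:
        summary = {
            "dataset_stats": {f.value: n for f, n in report.dataset_stats.items()},
            "n_records": len(report.per_record),
            "n_flagged": report.n_flagged,
            "frequent_locations": [
                {"latitude": lat, "longitude": lon, "count": count}
                for lat, lon, count in report.frequent_locations
            ],
            "unparseable_ids": report.unparseable_ids,
        }
        Path(summary_path).write_text(json.dumps(summary, indent=2) + "\n", encoding="utf-8")


def read_pairs(path: str | os.PathLike, delimiter: str | None = None
               ) -> list[tuple[float | None, float | None]]:
    """Read a two-column numeric CSV/TSV for correlation analysis; blank
    cells become None (missing)."""
    sep = infer_delimiter(path, delimiter)
    try:
        frame = pd.read_csv(path, sep=sep, encoding="utf-8")
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise InputError(f"cannot read pairs file {path}: {exc}") from None
    if frame.shape[1] < 2:
        raise InputError(f"pairs file {path} needs at least two columns")
    x = frame.iloc[:, 0]
    y = frame.iloc[:, 1]
    return [
        (None if pd.isna(a) else float(a), None if pd.isna(b) else float(b))
        for a, b in zip(x, y)
    ]
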