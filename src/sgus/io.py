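"""Cohort CSV and model-file readers/writers.

One cohort schema serves all commands: CSV with a header, one row per
patient.  Columns: ``patient_id``; twelve finding columns named
``<pg|smg>_<l|r>_<hypo|band|irreg>``; the five ACR/EULAR item columns;
and four label columns.  Finding values are 0/1; item values are 0/1 or
``unknown``; labels are ``SS``/``nonSS``/``unknown`` (subtype:
``primary``/``secondary``/``none``/``unknown``).  Item and label columns
are optional — commands that need them fail fast with the missing column
named.

US models are stored as versioned YAML so refit models can be dropped in
wherever the built-in constants are used.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import yaml

from .cohort import (
    FINDINGS,
    GLAND_TYPES,
    ITEMS,
    SIDES,
    STATUSES,
    SUBTYPES,
    AcrEularItems,
    GlandFindings,
    PatientRecord,
)
from .errors import CohortValidationError, DataError
from .us_scoring import GlandModel, UsModel

MODEL_SCHEMA_VERSION = 1

_GLAND_PREFIX = {
    ("parotid", "left"): "pg_l",
    ("parotid", "right"): "pg_r",
    ("submandibular", "left"): "smg_l",
    ("submandibular", "right"): "smg_r",
}
_FINDING_SUFFIX = {
    "hypoechoic_area": "hypo",
    "hyperechoic_band": "band",
    "irregular_border": "irreg",
}

FINDING_COLUMNS = [
    f"{_GLAND_PREFIX[(gt, s)]}_{_FINDING_SUFFIX[f]}"
    for gt in GLAND_TYPES
    for s in SIDES
    for f in FINDINGS
]
ITEM_COLUMNS = list(ITEMS)
LABEL_COLUMNS = ["clinical_ss", "aecg_ss", "acr_ss", "ss_subtype"]
ALL_COLUMNS = ["patient_id"] + FINDING_COLUMNS + ITEM_COLUMNS + LABEL_COLUMNS


def _parse_binary(value: str) -> int:
    v = value.strip()
    if v in ("0", "1"):
        return int(v)
    raise ValueError(f"expected 0 or 1, got {value!r}")


def _parse_item(value: str) -> Optional[int]:
    v = value.strip()
    if v in ("", "unknown", "NA"):
        return None
    return _parse_binary(v)


def read_cohort(path) -> List[PatientRecord]:
    """Read and validate a cohort CSV.

    Raises :class:`CohortValidationError` listing every offending cell with
    its file line number and column, and :class:`DataError` for structural
    problems (missing required columns, duplicate patient ids).
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in ["patient_id"] + FINDING_COLUMNS if c not in header]
        if missing:
            raise DataError(f"{path}: missing required column(s): {missing}")
        has_items = [c for c in ITEM_COLUMNS if c in header]
        rows = list(reader)

    errors = []
    records = []
    seen_ids = {}
    for i, row in enumerate(rows):
        line = i + 2  # 1-based, after the header
        pid = (row.get("patient_id") or "").strip()
        if not pid:
            errors.append((line, "patient_id", "empty patient_id"))
            continue
        if pid in seen_ids:
            raise DataError(
                f"{path}: duplicate patient_id {pid!r} at lines "
                f"{seen_ids[pid]} and {line}"
            )
        seen_ids[pid] = line

        glands = []
        row_ok = True
        for gt in GLAND_TYPES:
            for s in SIDES:
                vals = {}
                for f in FINDINGS:
                    col = f"{_GLAND_PREFIX[(gt, s)]}_{_FINDING_SUFFIX[f]}"
                    try:
                        vals[f] = _parse_binary(row.get(col) or "")
                    except ValueError as exc:
                        errors.append((line, col, str(exc)))
                        row_ok = False
                if row_ok:
                    glands.append(GlandFindings(gland_type=gt, side=s, **vals))
        items = None
        if has_items:
            item_vals = {}
            for col in ITEM_COLUMNS:
                raw = row.get(col) if col in (row or {}) else None
                try:
                    item_vals[col] = _parse_item(raw if raw is not None else "")
                except ValueError as exc:
                    errors.append((line, col, str(exc)))
                    row_ok = False
            if row_ok:
                items = AcrEularItems(**item_vals)
        labels = {}
        for col in LABEL_COLUMNS:
            raw = (row.get(col) or "unknown").strip() or "unknown"
            valid = SUBTYPES if col == "ss_subtype" else STATUSES
            if raw not in valid:
                errors.append((line, col, f"expected one of {valid}, got {raw!r}"))
                row_ok = False
            else:
                labels[col] = raw
        if row_ok:
            records.append(
                PatientRecord(patient_id=pid, glands=tuple(glands), items=items, **labels)
            )
    if errors:
        raise CohortValidationError(errors)
    return records


def write_cohort(cohort: Sequence[PatientRecord], path) -> None:
    """Write a cohort CSV (inverse of :func:`read_cohort`)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(ALL_COLUMNS)
        for p in cohort:
            row = [p.patient_id]
            for gt in GLAND_TYPES:
                for s in SIDES:
                    g = p.gland(gt, s)
                    row.extend(g.value(f) for f in FINDINGS)
            for item in ITEMS:
                v = getattr(p.items, item) if p.items is not None else None
                row.append("unknown" if v is None else v)
            row.extend([p.clinical_ss, p.aecg_ss, p.acr_ss, p.ss_subtype])
            writer.writerow(row)


def write_model(model: UsModel, path) -> None:
    """Serialize a US model to versioned YAML."""
    doc = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "basis": model.basis,
        "version": model.version,
        "glands": {
            gt: {
                "intercept": float(model.glands[gt].intercept),
                "coefficients": {
                    f: float(b) for f, b in model.glands[gt].coefficients.items()
                },
            }
            for gt in GLAND_TYPES
        },
        "grade_intervals": [list(iv) for iv in model.grade_intervals],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_model(path, expected_basis: Optional[str] = None) -> UsModel:
    """Load a US model file, refusing schema or basis mismatches."""
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise DataError(f"{path}: not a model file")
    if doc.get("schema_version") != MODEL_SCHEMA_VERSION:
        raise DataError(
            f"{path}: unsupported schema_version {doc.get('schema_version')!r}"
        )
    basis = doc.get("basis")
    if expected_basis is not None and basis != expected_basis.upper():
        raise DataError(
            f"{path}: model basis {basis!r} does not match requested "
            f"{expected_basis.upper()!r}"
        )
    glands = {
        gt: GlandModel(
            intercept=float(spec["intercept"]),
            coefficients={f: float(b) for f, b in spec["coefficients"].items()},
        )
        for gt, spec in doc["glands"].items()
    }
    return UsModel(
        basis=basis,
        glands=glands,
        grade_intervals=tuple(tuple(iv) for iv in doc["grade_intervals"]),
        version=str(doc.get("version", "file")),
    )
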