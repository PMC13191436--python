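"""Reading and writing the delimited text formats of the pipeline.

All tables are plain CSV/TSV (comma, tab or semicolon auto-detected, decimal
point only).  The literal ``-``/``–`` or an empty cell in a threshold column
parses as a *missing* threshold; such records are retained and flagged.
"""

from __future__ import annotations

import csv
import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    FORM_NONE,
    AnalyteTable,
    FormatError,
    ScoreTable,
    ThresholdDB,
    ValidationError,
    canonical_name,
    display_name,
    split_form,
)

__all__ = [
    "read_analyte_table",
    "write_analyte_table",
    "read_threshold_db",
    "write_threshold_db",
    "read_score_table",
    "write_score_table",
]

_ANALYTE_ALIASES = {
    "analyte": "analyte_id",
    "analyte_id": "analyte_id",
    "compound": "analyte_id",
    "compound_name": "analyte_id",
    "compoundname": "analyte_id",
    "name": "analyte_id",
    "sensor": "analyte_id",
    "form": "form",
    "group": "sample_group",
    "sample": "sample_group",
    "sample_group": "sample_group",
    "replicate": "replicate",
    "rep": "replicate",
    "value": "value",
    "content": "value",
    "concentration": "value",
    "relative_content": "value",
    "response": "value",
    "score": "score",
    "classification": "classification",
    "sd": "sd",
    "std": "sd",
    "threshold": "threshold",
    "descriptor": "descriptor",
    "odor_characteristics": "descriptor",
    "taste_class": "taste_class",
    "modality": "modality",
    "score_kind": "score_kind",
}

_MISSING = {"", "-", "–", "—", "na", "nan", "n/a", "nd"}


def _read_delimited(path) -> pd.DataFrame:
    """Read a delimited text file with delimiter sniffing and header aliasing."""
    text = Path(path).read_text(encoding="utf-8")
    if not text.strip():
        raise FormatError(f"{path}: empty file")
    try:
        dialect = csv.Sniffer().sniff(text.splitlines()[0], delimiters=",\t;")
        sep = dialect.delimiter
    except csv.Error:
        sep = ","
    df = pd.read_csv(_io.StringIO(text), sep=sep, dtype=str, keep_default_na=False)
    df.columns = [
        _ANALYTE_ALIASES.get(c.strip().casefold().replace(" ", "_"), c.strip())
        for c in df.columns
    ]
    return df


def _parse_float(cell: str, *, allow_missing: bool, what: str, where: str) -> float:
    s = str(cell).strip()
    if s.casefold() in _MISSING:
        if allow_missing:
            return np.nan
        raise ValidationError(f"{where}: missing {what}")
    try:
        return float(s)
    except ValueError as exc:
        raise FormatError(f"{where}: cannot parse {what} {cell!r}") from exc


def read_analyte_table(path, value_kind: str) -> AnalyteTable:
    """Read an :class:`AnalyteTable` from delimited text.

    Required columns: analyte name, sample group, value; optional columns:
    form, replicate, sd.  Trailing ``-M``/``-D`` name suffixes are split
    into ``(analyte_id, form)`` when no explicit form column is present.
    """
    df = _read_delimited(path)
    for col in ("analyte_id", "sample_group", "value"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    out = {}
    if "form" in df.columns:
        out["analyte_id"] = df["analyte_id"]
        out["form"] = df["form"].replace("", FORM_NONE)
    else:
        stems, forms = zip(*(split_form(n) for n in df["analyte_id"]))
        out["analyte_id"], out["form"] = list(stems), list(forms)
    out["sample_group"] = df["sample_group"]
    out["replicate"] = (
        [int(r) if str(r).strip() else None for r in df["replicate"]]
        if "replicate" in df.columns
        else pd.NA
    )
    out["value"] = [
        _parse_float(v, allow_missing=False, what="value", where=f"{path} row {i + 2}")
        for i, v in enumerate(df["value"])
    ]
    out["sd"] = (
        [
            _parse_float(v, allow_missing=True, what="sd", where=f"{path} row {i + 2}")
            for i, v in enumerate(df["sd"])
        ]
        if "sd" in df.columns
        else np.nan
    )
    return AnalyteTable(pd.DataFrame(out), value_kind)


def write_analyte_table(table: AnalyteTable, path) -> None:
    """Write an :class:`AnalyteTable` as CSV (stable column order)."""
    df = table.data.copy()
    df["replicate"] = df["replicate"].astype(object).where(df["replicate"].notna(), "")
    df.to_csv(path, index=False, float_format="%.10g")


def read_threshold_db(path, modality: str) -> ThresholdDB:
    """Read a :class:`ThresholdDB` from delimited text.

    Rows may name per-form signals (``1-Hexanal-D``); the form marker is
    stripped and duplicate per-form rows are collapsed when their thresholds
    agree (they name the same compound).  ``-``/empty threshold cells parse
    as missing; ``threshold <= 0`` is a validation error.
    """
    df = _read_delimited(path)
    for col in ("analyte_id", "threshold"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    rows: dict[str, dict] = {}
    for i, raw in df.iterrows():
        stem, _ = split_form(raw["analyte_id"])
        thr = _parse_float(
            raw["threshold"], allow_missing=True, what="threshold",
            where=f"{path} row {i + 2}",
        )
        if not np.isnan(thr) and thr <= 0:
            raise ValidationError(
                f"{path} row {i + 2}: non-positive threshold for {stem!r}"
            )
        rec = {
            "analyte_id": stem,
            "threshold": thr,
            "descriptor": str(raw.get("descriptor", "") or ""),
            "taste_class": str(raw.get("taste_class", "") or ""),
        }
        key = canonical_name(stem)
        if key in rows:
            old = rows[key]["threshold"]
            same = (np.isnan(old) and np.isnan(thr)) or old == thr
            if not same:
                raise ValidationError(
                    f"{path}: conflicting thresholds for {stem!r} ({old} vs {thr})"
                )
        else:
            rows[key] = rec
    return ThresholdDB(pd.DataFrame(list(rows.values())), modality)


def write_threshold_db(db: ThresholdDB, path) -> None:
    df = db.data.copy()
    df.insert(1, "modality", db.modality)
    df.to_csv(path, index=False, float_format="%.10g")


def write_score_table(table: ScoreTable, path) -> None:
    """Write a :class:`ScoreTable` as CSV.

    Rows excluded for a missing threshold are emitted with an explicit
    ``NA`` score so the exclusion is visible in the output file.
    """
    df = table.data.copy()
    df.insert(0, "label", [
        display_name(a, f) for a, f in zip(df["analyte_id"], df["form"])
    ])
    df.insert(1, "score_kind", table.score_kind)
    df["score"] = df["score"].map(lambda v: "NA" if np.isnan(v) else f"{v:.10g}")
    df.to_csv(path, index=False)


def read_score_table(path) -> ScoreTable:
    df = _read_delimited(path)
    for col in ("analyte_id", "sample_group", "score", "classification", "score_kind"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    kinds = set(df["score_kind"])
    if len(kinds) != 1:
        raise FormatError(f"{path}: mixed score kinds {sorted(kinds)}")
    out = pd.DataFrame(
        {
            "analyte_id": df["analyte_id"],
            "form": df["form"].replace("", FORM_NONE) if "form" in df.columns else FORM_NONE,
            "sample_group": df["sample_group"],
            "score": [
                _parse_float(v, allow_missing=True, what="score", where=f"{path} row {i + 2}")
                for i, v in enumerate(df["score"])
            ],
            "classification": df["classification"],
        }
    )
    return ScoreTable(out, kinds.pop())
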