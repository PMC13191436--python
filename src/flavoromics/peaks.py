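"""Volatile peak-table bookkeeping: semi-quantification, deduplication,
class aggregation.

GC-IMS peak tables are semi-quantified by normalization: each signal is
expressed as a percentage of the within-sample total.  A compound may appear
as two signals (monomer and proton-bound dimer); counting unique compounds
merges the two by name stem.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import AnalyteTable, ValidationError, canonical_name

__all__ = [
    "normalize_to_relative_content",
    "deduplicate_forms",
    "aggregate_classes",
    "read_class_map",
]

CHEMICAL_CLASSES = (
    "aldehyde", "ketone", "alcohol", "ester", "ether",
    "olefin", "heterocyclic", "other",
)


class NormalizationError(ValidationError):
    """Raised when a sample cannot be normalized (all-zero signal)."""


def normalize_to_relative_content(raw: AnalyteTable) -> AnalyteTable:
    """Convert raw intensities/concentrations to relative content (%).

    Each value is divided by the within-sample total (per sample group and
    replicate) and multiplied by 100, so per-sample values sum to 100.
    Normalizing an already-normalized table is a no-op.
    """
    df = raw.data.copy()
    keys = [df["sample_group"], df["replicate"].fillna(-1)]
    totals = df.groupby(keys, sort=False)["value"].transform("sum")
    zero = totals <= 0
    if zero.any():
        sample = df.loc[zero.idxmax(), "sample_group"]
        raise NormalizationError(f"all-zero sample {sample!r}: cannot normalize")
    df["value"] = df["value"] / totals * 100.0
    df["sd"] = np.nan  # printed SDs do not survive rescaling
    return AnalyteTable(df, "relative_percent")


def deduplicate_forms(table: AnalyteTable) -> list[str]:
    """Unique compound names after merging monomer/dimer signals.

    Order is first appearance; matching is case-insensitive.  Never
    increases the count and is invariant to row order up to ordering of the
    result.
    """
    seen: dict[str, str] = {}
    for name in table.data["analyte_id"]:
        seen.setdefault(canonical_name(name), name)
    return list(seen.values())


def read_class_map(path) -> dict[str, str]:
    """Read a two-column CSV (analyte, chemical_class) into a class map."""
    df = pd.read_csv(path)
    df.columns = [c.strip().casefold() for c in df.columns]
    name_col = next(c for c in df.columns if c in ("analyte", "analyte_id", "compound"))
    cls_col = next(c for c in df.columns if "class" in c)
    out = {}
    for a, c in zip(df[name_col], df[cls_col]):
        c = str(c).strip().casefold()
        if c not in CHEMICAL_CLASSES:
            raise ValidationError(f"unknown chemical class {c!r} for {a!r}")
        out[canonical_name(a)] = c
    return out


def aggregate_classes(
    table: AnalyteTable, classes: dict[str, str] | None
) -> pd.DataFrame:
    """Per-class per-sample totals with compound counts.

    Unmapped analytes fall into class ``other``.  Returns a DataFrame
    indexed by chemical class with one column per sample group plus an
    ``n_compounds`` column (unique compounds after monomer/dimer merging).
    Class totals are conservative: summed over classes they reproduce the
    per-sample totals.
    """
    classes = classes or {}
    df = table.data.copy()
    df["chemical_class"] = [
        classes.get(canonical_name(a), "other") for a in df["analyte_id"]
    ]
    totals = df.pivot_table(
        index="chemical_class",
        columns="sample_group",
        values="value",
        aggfunc="sum",
        sort=False,
    )
    counts = (
        df.assign(stem=df["analyte_id"].map(canonical_name))
        .groupby("chemical_class", sort=False)["stem"]
        .nunique()
    )
    totals.insert(0, "n_compounds", counts)
    order = [c for c in CHEMICAL_CLASSES if c in totals.index]
    return totals.loc[order]
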