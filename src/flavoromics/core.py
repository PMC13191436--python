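"""Core tabular containers for flavor-compound bookkeeping.

Two kinds of tables travel through the whole pipeline:

* :class:`AnalyteTable` — concentrations (mg/kg) or normalized relative
  contents (%) of named analytes per sample group (and, for replicate-level
  data, per replicate).  GC-IMS analytes may occur twice, as a monomer and a
  proton-bound dimer of the same compound; the ``form`` column keeps the two
  signals apart while name-based deduplication can merge them again.
* :class:`ThresholdDB` — per-compound taste or odor thresholds (mg/kg) with
  optional odor descriptors and taste-class tags.  Missing thresholds are
  kept (as NaN) rather than dropped so that downstream scoring can report
  exclusions explicitly.

Scores (TAV/ROAV) live in :class:`ScoreTable`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FORM_NONE",
    "FORM_MONOMER",
    "FORM_DIMER",
    "FormatError",
    "ValidationError",
    "canonical_name",
    "split_form",
    "display_name",
    "AnalyteTable",
    "ThresholdDB",
    "ScoreTable",
]

FORM_NONE = "none"
FORM_MONOMER = "monomer"
FORM_DIMER = "dimer"

VALUE_KINDS = ("concentration_mg_per_kg", "relative_percent")
TASTE_CLASSES = ("umami", "sweet", "bitter", "aromatic")

# key / modifier / negligible / excluded_no_threshold
CLASSIFICATIONS = ("key", "modifier", "negligible", "excluded_no_threshold")

_FORM_SUFFIX = re.compile(r"[-\s]([MD])$", re.IGNORECASE)
_WS = re.compile(r"\s+")


class FormatError(ValueError):
    """Raised when an input file does not have the expected shape."""


class ValidationError(ValueError):
    """Raised when parsed data violates a table invariant."""


def canonical_name(name: str) -> str:
    """Canonical matching key for an analyte name.

    Matching is case-insensitive with internal whitespace collapsed;
    stereo-descriptor prefixes such as ``(E)-``/``(Z)-`` are preserved
    because they distinguish real compounds.
    """
    return _WS.sub(" ", str(name).strip()).casefold()


def split_form(name: str) -> tuple[str, str]:
    """Split a trailing ``-M``/``-D`` monomer/dimer marker off a compound name.

    >>> split_form("1-Nonanal-D")
    ('1-Nonanal', 'dimer')
    >>> split_form("Heptanal")
    ('Heptanal', 'none')
    """
    name = _WS.sub(" ", str(name).strip())
    m = _FORM_SUFFIX.search(name)
    if m is None:
        return name, FORM_NONE
    stem = name[: m.start()]
    form = FORM_MONOMER if m.group(1).upper() == "M" else FORM_DIMER
    return stem, form


def display_name(analyte_id: str, form: str) -> str:
    """Re-attach the ``-M``/``-D`` marker for printing."""
    if form == FORM_MONOMER:
        return f"{analyte_id}-M"
    if form == FORM_DIMER:
        return f"{analyte_id}-D"
    return analyte_id


_ANALYTE_COLUMNS = ["analyte_id", "form", "sample_group", "replicate", "value", "sd"]


@dataclass
class AnalyteTable:
    """Long-format analyte measurements.

    ``data`` columns: ``analyte_id`` (str), ``form`` (none/monomer/dimer),
    ``sample_group`` (str), ``replicate`` (nullable int), ``value`` (float,
    >= 0), ``sd`` (float >= 0 or NaN; printed SD when only group means
    exist).  All rows of one table share a single ``value_kind``.
    """

    data: pd.DataFrame
    value_kind: str

    def __post_init__(self) -> None:
        if self.value_kind not in VALUE_KINDS:
            raise ValidationError(f"unknown value_kind {self.value_kind!r}")
        df = self.data.copy()
        for col in _ANALYTE_COLUMNS:
            if col not in df.columns:
                if col == "form":
                    df["form"] = FORM_NONE
                elif col == "replicate":
                    df["replicate"] = pd.NA
                elif col == "sd":
                    df["sd"] = np.nan
                else:
                    raise FormatError(f"AnalyteTable missing column {col!r}")
        df = df[_ANALYTE_COLUMNS]
        df["analyte_id"] = df["analyte_id"].astype(str)
        df["sample_group"] = df["sample_group"].astype(str)
        df["replicate"] = df["replicate"].astype("Int64")
        df["value"] = df["value"].astype(float)
        df["sd"] = df["sd"].astype(float)
        bad_form = ~df["form"].isin([FORM_NONE, FORM_MONOMER, FORM_DIMER])
        if bad_form.any():
            raise ValidationError(
                f"invalid form labels: {sorted(df.loc[bad_form, 'form'].unique())}"
            )
        if df["value"].isna().any():
            raise ValidationError("missing values in 'value' column")
        neg = df.index[df["value"] < 0]
        if len(neg):
            row = df.loc[neg[0]]
            raise ValidationError(
                f"negative value {row['value']} for analyte "
                f"{row['analyte_id']!r} in sample {row['sample_group']!r}"
            )
        if (df["sd"].dropna() < 0).any():
            raise ValidationError("negative sd")
        key = df[["analyte_id", "form", "sample_group", "replicate"]].apply(
            lambda r: (canonical_name(r.iloc[0]), r.iloc[1], r.iloc[2], r.iloc[3]),
            axis=1,
        )
        if key.duplicated().any():
            dup = df.loc[key.duplicated(), ["analyte_id", "sample_group"]].iloc[0]
            raise ValidationError(
                f"duplicate entry for ({dup['analyte_id']}, {dup['sample_group']})"
            )
        self.data = df.reset_index(drop=True)

    # -- convenience ----------------------------------------------------
    @property
    def groups(self) -> list[str]:
        """Sample groups in first-appearance order."""
        return list(dict.fromkeys(self.data["sample_group"]))

    @property
    def entries(self) -> pd.DataFrame:
        """Unique (analyte_id, form) pairs in first-appearance order."""
        return self.data[["analyte_id", "form"]].drop_duplicates().reset_index(drop=True)

    def pivot(self, aggregate: str = "mean") -> pd.DataFrame:
        """Wide (analyte_id, form) x sample_group matrix of values.

        Replicates, when present, are aggregated with ``aggregate``.
        """
        return self.data.pivot_table(
            index=["analyte_id", "form"],
            columns="sample_group",
            values="value",
            aggfunc=aggregate,
            sort=False,
        )

    def subset(self, analyte_ids) -> "AnalyteTable":
        keys = {canonical_name(a) for a in analyte_ids}
        mask = self.data["analyte_id"].map(canonical_name).isin(keys)
        return AnalyteTable(self.data.loc[mask], self.value_kind)

    def equals(self, other: "AnalyteTable", rtol: float = 1e-6) -> bool:
        if self.value_kind != other.value_kind:
            return False
        a, b = self.data, other.data
        if len(a) != len(b):
            return False
        cat = ["analyte_id", "form", "sample_group"]
        if not a[cat].reset_index(drop=True).equals(b[cat].reset_index(drop=True)):
            return False
        if not a["replicate"].fillna(-1).reset_index(drop=True).equals(
            b["replicate"].fillna(-1).reset_index(drop=True)
        ):
            return False
        for col in ("value", "sd"):
            x, y = a[col].to_numpy(float), b[col].to_numpy(float)
            ok = np.isclose(x, y, rtol=rtol, equal_nan=True)
            if not ok.all():
                return False
        return True


@dataclass
class ThresholdDB:
    """Per-analyte taste or odor thresholds.

    ``data`` columns: ``analyte_id``, ``modality`` (taste/odor),
    ``threshold`` (mg/kg, > 0 or NaN for missing), ``descriptor`` (odor
    character, optional), ``taste_class`` (pipe-separated subset of
    umami/sweet/bitter/aromatic, optional).  One record per analyte;
    thresholds are form-agnostic (monomer and dimer signals of one compound
    share the compound's threshold).
    """

    data: pd.DataFrame
    modality: str

    def __post_init__(self) -> None:
        if self.modality not in ("taste", "odor"):
            raise ValidationError(f"unknown modality {self.modality!r}")
        df = self.data.copy()
        if "analyte_id" not in df.columns:
            raise FormatError("ThresholdDB missing column 'analyte_id'")
        if "threshold" not in df.columns:
            raise FormatError("ThresholdDB missing column 'threshold'")
        if "descriptor" not in df.columns:
            df["descriptor"] = ""
        if "taste_class" not in df.columns:
            df["taste_class"] = ""
        df = df[["analyte_id", "threshold", "descriptor", "taste_class"]]
        df["analyte_id"] = df["analyte_id"].astype(str)
        df["threshold"] = df["threshold"].astype(float)
        df["descriptor"] = df["descriptor"].fillna("").astype(str)
        df["taste_class"] = df["taste_class"].fillna("").astype(str)
        bad = df["threshold"].dropna() <= 0
        if bad.any():
            a = df.loc[bad[bad].index[0], "analyte_id"]
            raise ValidationError(f"non-positive threshold for {a!r}")
        for tc in df["taste_class"]:
            for part in filter(None, tc.split("|")):
                if part not in TASTE_CLASSES:
                    raise ValidationError(f"unknown taste class {part!r}")
        if df["analyte_id"].map(canonical_name).duplicated().any():
            raise ValidationError("duplicate analyte in ThresholdDB")
        self.data = df.reset_index(drop=True)
        self._lookup = {
            canonical_name(a): t
            for a, t in zip(df["analyte_id"], df["threshold"])
        }

    def threshold_for(self, analyte_id: str) -> float:
        """Threshold in mg/kg, or NaN if unknown/missing."""
        return self._lookup.get(canonical_name(analyte_id), np.nan)

    def has_threshold(self, analyte_id: str) -> bool:
        return not np.isnan(self.threshold_for(analyte_id))

    def taste_classes_for(self, analyte_id: str) -> frozenset[str]:
        key = canonical_name(analyte_id)
        for a, tc in zip(self.data["analyte_id"], self.data["taste_class"]):
            if canonical_name(a) == key:
                return frozenset(filter(None, tc.split("|")))
        return frozenset()

    @property
    def missing(self) -> list[str]:
        """Analytes retained with no threshold (flagged, not dropped)."""
        return list(self.data.loc[self.data["threshold"].isna(), "analyte_id"])


@dataclass
class ScoreTable:
    """TAV or ROAV scores per (analyte, form, sample_group).

    ``data`` columns: ``analyte_id``, ``form``, ``sample_group``, ``score``
    (>= 0, NaN when the analyte has no threshold), ``classification``.
    ``excluded_no_threshold`` rows are exactly the rows with NaN score.
    """

    data: pd.DataFrame
    score_kind: str
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.score_kind not in ("TAV", "ROAV"):
            raise ValidationError(f"unknown score_kind {self.score_kind!r}")
        df = self.data.copy()
        needed = ["analyte_id", "form", "sample_group", "score", "classification"]
        for col in needed:
            if col not in df.columns:
                if col == "form":
                    df["form"] = FORM_NONE
                else:
                    raise FormatError(f"ScoreTable missing column {col!r}")
        df = df[needed]
        df["score"] = df["score"].astype(float)
        if (df["score"].dropna() < 0).any():
            raise ValidationError("negative score")
        bad = ~df["classification"].isin(CLASSIFICATIONS)
        if bad.any():
            raise ValidationError(
                f"unknown classification {df.loc[bad, 'classification'].iloc[0]!r}"
            )
        excl = df["classification"] == "excluded_no_threshold"
        if not (excl == df["score"].isna()).all():
            raise ValidationError(
                "excluded_no_threshold must coincide with missing scores"
            )
        self.data = df.reset_index(drop=True)

    def pivot(self) -> pd.DataFrame:
        return self.data.pivot_table(
            index=["analyte_id", "form"],
            columns="sample_group",
            values="score",
            sort=False,
        )

    def equals(self, other: "ScoreTable", rtol: float = 1e-6) -> bool:
        if self.score_kind != other.score_kind:
            return False
        a, b = self.data, other.data
        if len(a) != len(b):
            return False
        cat = ["analyte_id", "form", "sample_group", "classification"]
        if not a[cat].reset_index(drop=True).equals(b[cat].reset_index(drop=True)):
            return False
        return bool(
            np.isclose(
                a["score"].to_numpy(float),
                b["score"].to_numpy(float),
                rtol=rtol,
                equal_nan=True,
            ).all()
        )
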