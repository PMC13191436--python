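"""Taste activity values (TAV) for non-volatile analytes.

TAV = C / T, the ratio of an analyte's concentration to its taste threshold
(both mg/kg, so TAV is dimensionless).  A compound with TAV > 1 in every
sample is a *key* taste substance; one reaching 0.1 <= TAV <= 1 in at least
one sample is a taste *modifier*; the rest are negligible.  Analytes with no
published threshold are carried through as ``excluded_no_threshold`` rather
than dropped.

The "key in every sample" rule matters: Arg crosses TAV = 1 in one sample
only, yet it behaves as a modifier overall; requiring TAV > 1 across all
samples keeps the key set to the analytes that are taste-active throughout.
The modifier rule is an "any sample" rule for the same reason in reverse
(Met dips below 0.1 in one sample but modifies taste elsewhere).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .core import AnalyteTable, ScoreTable, ThresholdDB, ValidationError

__all__ = ["compute_tav", "tav_table", "aggregate_taste_classes"]

DEFAULT_KEY_CUT = 1.0
DEFAULT_MODIFIER_CUT = 0.1


def compute_tav(concentration: float, threshold: float) -> float:
    """TAV of a single analyte: concentration / threshold.

    Returns NaN (the excluded-no-threshold marker) when the threshold is
    missing.  Homogeneous of degree zero: scaling both inputs by the same
    factor leaves the TAV unchanged.
    """
    if threshold is None or (isinstance(threshold, float) and math.isnan(threshold)):
        return math.nan
    if threshold <= 0:
        raise ValidationError(f"non-positive threshold {threshold}")
    if concentration < 0:
        raise ValidationError(f"negative concentration {concentration}")
    return concentration / threshold


def tav_table(
    table: AnalyteTable,
    db: ThresholdDB,
    key_cut: float = DEFAULT_KEY_CUT,
    modifier_cut: float = DEFAULT_MODIFIER_CUT,
) -> ScoreTable:
    """Score every (analyte, sample) and classify analytes.

    Classification per analyte (applied to all its rows):

    * ``key`` — TAV > ``key_cut`` in *every* sample group;
    * ``modifier`` — not key, and ``modifier_cut`` <= TAV <= ``key_cut``
      in at least one sample group;
    * ``negligible`` — otherwise;
    * ``excluded_no_threshold`` — no threshold in ``db``.

    Replicates, if present, are averaged to group means before scoring.
    """
    if table.value_kind != "concentration_mg_per_kg":
        raise ValidationError("TAV requires concentrations in mg/kg")
    wide = table.pivot()
    rows = []
    for (analyte, form), conc in wide.iterrows():
        thr = db.threshold_for(analyte)
        scores = {g: compute_tav(c, thr) for g, c in conc.dropna().items()}
        vals = list(scores.values())
        if np.isnan(thr):
            cls = "excluded_no_threshold"
        elif all(v > key_cut for v in vals):
            cls = "key"
        elif any(modifier_cut <= v <= key_cut for v in vals):
            cls = "modifier"
        else:
            cls = "negligible"
        for g, s in scores.items():
            rows.append(
                {"analyte_id": analyte, "form": form, "sample_group": g,
                 "score": s, "classification": cls}
            )
    out = ScoreTable(pd.DataFrame(rows), "TAV")
    out.extra["key_compounds"] = sorted(
        out.data.loc[out.data["classification"] == "key", "analyte_id"].unique()
    )
    out.extra["modifier_compounds"] = sorted(
        out.data.loc[out.data["classification"] == "modifier", "analyte_id"].unique()
    )
    return out


def aggregate_taste_classes(table: AnalyteTable, db: ThresholdDB) -> pd.DataFrame:
    """Per-taste-class per-sample concentration totals (mg/kg).

    Taste classes come from ``db``; an analyte tagged with several classes
    (Arg is both sweet and bitter) contributes to each.  A ``total`` row
    sums every analyte in the table once, including analytes with no taste
    class.
    """
    if table.value_kind != "concentration_mg_per_kg":
        raise ValidationError("taste-class totals require concentrations in mg/kg")
    wide = table.pivot()
    groups = wide.columns
    out: dict[str, pd.Series] = {}
    for (analyte, _form), conc in wide.iterrows():
        for tc in db.taste_classes_for(analyte):
            out[tc] = out.get(tc, pd.Series(0.0, index=groups)) + conc.fillna(0.0)
    res = pd.DataFrame(out).T if out else pd.DataFrame(columns=groups)
    res.loc["total"] = wide.sum(axis=0)
    res.index.name = "taste_class"
    return res
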