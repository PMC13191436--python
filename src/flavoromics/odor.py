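"""Relative odor activity values (ROAV) and key-odorant screening.

For each sample the compound with the largest ratio of relative content to
odor threshold contributes the most to the aroma; its ROAV is fixed at 100
and every other compound is scored relative to it:

    ROAV_i = (C%_i / C%_ref) * (T_ref / T_i) * 100

where C% is the relative content (%) and T the odor threshold (mg/kg).
Compounds reaching ROAV >= 1 (any monomer/dimer form, any sample) are key
odorants; a maximum merged ROAV in [0.1, 1) marks an odor modifier.

Thresholds are form-agnostic (the monomer and dimer of one compound share
its threshold), but scores are computed per signal because the two forms
carry different relative contents.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    AnalyteTable,
    ScoreTable,
    ThresholdDB,
    ValidationError,
    canonical_name,
    display_name,
)

__all__ = ["RoavResult", "select_reference", "compute_roav", "screen_roav"]

DEFAULT_KEY_CUT = 1.0
DEFAULT_MODIFIER_CUT = 0.1


@dataclass
class RoavResult:
    """ROAV scores plus the per-sample reference compound."""

    references: dict[str, tuple[str, str]]  # sample_group -> (analyte_id, form)
    scores: ScoreTable
    key_compounds: list[str] = field(default_factory=list)
    modifier_compounds: list[str] = field(default_factory=list)

    def reference_name(self, group: str) -> str:
        return display_name(*self.references[group])


def select_reference(
    table: AnalyteTable, db: ThresholdDB, sample_group: str | None = None
) -> tuple[str, str]:
    """Argmax of relative content / odor threshold within one sample.

    Analytes with a missing threshold are skipped.  Ties break to the
    lexicographically first display name, so selection is deterministic.
    """
    df = table.data
    if sample_group is not None:
        df = df[df["sample_group"] == sample_group]
    if df.empty:
        raise ValidationError(f"no rows for sample {sample_group!r}")
    best: tuple[float, str, tuple[str, str]] | None = None
    for _, row in df.iterrows():
        thr = db.threshold_for(row["analyte_id"])
        if np.isnan(thr):
            continue
        ratio = row["value"] / thr
        name = display_name(row["analyte_id"], row["form"])
        cand = (ratio, name, (row["analyte_id"], row["form"]))
        if best is None or ratio > best[0] or (ratio == best[0] and name < best[1]):
            best = cand
    if best is None:
        raise ValidationError("no analyte with a known odor threshold")
    return best[2]


def compute_roav(
    table: AnalyteTable,
    db: ThresholdDB,
    reference: str | tuple[str, str] | None = None,
    key_cut: float = DEFAULT_KEY_CUT,
    modifier_cut: float = DEFAULT_MODIFIER_CUT,
    merge_forms: bool = True,
) -> RoavResult:
    """Score every (analyte, form, sample) against the reference compound.

    ``reference=None`` selects the per-sample argmax of content/threshold
    (the reference may then differ between samples); a fixed reference can
    be given as a display name (``"1-Octanal-M"``) or ``(analyte_id, form)``
    pair.  The reference scores exactly 100 in its own sample.  Analytes
    with a missing threshold are carried as ``excluded_no_threshold``.

    Screening (``key_cut``/``modifier_cut``/``merge_forms``) is applied via
    :func:`screen_roav` and stored on the result.
    """
    if table.value_kind != "relative_percent":
        raise ValidationError("ROAV requires normalized relative contents (%)")
    wide = table.pivot()
    groups = list(wide.columns)

    if reference is not None and not isinstance(reference, tuple):
        from .core import split_form

        reference = split_form(reference)

    references: dict[str, tuple[str, str]] = {}
    rows = []
    for g in groups:
        ref = reference if reference is not None else select_reference(table, db, g)
        ref_thr = db.threshold_for(ref[0])
        if np.isnan(ref_thr):
            raise ValidationError(f"reference {ref} has no odor threshold")
        try:
            ref_content = wide.loc[ref, g]
        except KeyError as exc:
            raise ValidationError(f"reference {ref} absent from table") from exc
        if not ref_content > 0:
            raise ValidationError(f"reference {ref} has zero content in {g!r}")
        references[g] = ref
        for (analyte, form), conc in wide[g].dropna().items():
            thr = db.threshold_for(analyte)
            if np.isnan(thr):
                score = np.nan
            else:
                score = (conc / ref_content) * (ref_thr / thr) * 100.0
            rows.append(
                {"analyte_id": analyte, "form": form, "sample_group": g,
                 "score": score}
            )
    df = pd.DataFrame(rows)
    df["classification"] = np.where(df["score"].isna(), "excluded_no_threshold",
                                    "negligible")
    scores = ScoreTable(df, "ROAV")
    result = RoavResult(references=references, scores=scores)
    result.key_compounds, result.modifier_compounds = screen_roav(
        result, merge_forms=merge_forms, key_cut=key_cut, modifier_cut=modifier_cut
    )
    # re-label rows with the screening outcome (per merged compound)
    key = {canonical_name(c) for c in result.key_compounds}
    mod = {canonical_name(c) for c in result.modifier_compounds}
    stems = df["analyte_id"].map(canonical_name)
    df.loc[stems.isin(key) & df["score"].notna(), "classification"] = "key"
    df.loc[stems.isin(mod) & df["score"].notna(), "classification"] = "modifier"
    result.scores = ScoreTable(df, "ROAV")
    return result


def screen_roav(
    result: RoavResult,
    merge_forms: bool = True,
    key_cut: float = DEFAULT_KEY_CUT,
    modifier_cut: float = DEFAULT_MODIFIER_CUT,
) -> tuple[list[str], list[str]]:
    """Key / modifier odorant lists from computed ROAVs.

    With ``merge_forms`` the monomer and dimer of one compound are screened
    together (a compound is key if *any* form in *any* sample reaches
    ``key_cut``); without it each form is screened as its own entry.  The
    key cut is inclusive (ROAV = 1.0 is key).  Lists are sorted by name.
    """
    df = result.scores.data.dropna(subset=["score"])
    if merge_forms:
        names = df["analyte_id"]
    else:
        names = [
            display_name(a, f) for a, f in zip(df["analyte_id"], df["form"])
        ]
    peak = (
        pd.DataFrame({"name": names, "score": df["score"].to_numpy()})
        .groupby("name", sort=False)["score"]
        .max()
    )
    keys = sorted(peak.index[peak >= key_cut])
    mods = sorted(peak.index[(peak >= modifier_cut) & (peak < key_cut)])
    return list(keys), list(mods)
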