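"""ROAV computation, reference selection, key-odorant screening.

The printed-score oracle check recomputes every ROAV from the fixture
relative contents and thresholds and compares with the published score
table.  Published inputs and outputs are rounded to 2 decimals, so the
comparison propagates a +/- 0.005 interval through the formula instead of
using a bare relative tolerance.  The butanal monomer/dimer rows are
asserted *swapped*: the published dimer scores are reproducible only from
the monomer contents and vice versa (consistent with swapped labels in one
of the two source tables); the package reproduces both tables as printed
and does not silently repair either.
"""

import numpy as np
import pandas as pd
import pytest

import flavoromics as fl
from flavoromics.odor import compute_roav, screen_roav, select_reference

# Published per-form ROAVs (groups A..E); rows printed as "<0.01" omitted.
PRINTED_ROAV = {
    "(Z)-4-Heptenal": [5.76, 3.81, 3.24, 2.91, 2.34],
    "Alpha-pinene": [0.01, 0.01, 0.01, 0.01, 0.01],
    "3-Methyl-1-butanol": [0.05, 0.04, 0.04, 0.04, 0.05],
    "1-Hexanal-D": [4.21, 6.18, 6.77, 6.85, 6.27],
    "1-Hexanal-M": [4.21, 4.40, 5.07, 4.34, 4.73],
    "1-Nonanal-D": [4.46, 6.51, 5.73, 6.52, 4.61],
    "1-Nonanal-M": [9.86, 11.98, 11.24, 10.46, 10.07],
    "1-Octanal-D": [54.46, 55.85, 48.47, 71.16, 49.64],
    "1-Octanal-M": [100.0, 100.0, 100.0, 100.0, 100.0],
    "1-Octen-3-ol-D": [23.34, 19.96, 22.74, 17.41, 15.50],
    "1-Octen-3-ol-M": [46.75, 41.35, 46.74, 41.03, 41.60],
    "1-Octen-3-one-D": [19.61, 16.23, 16.54, 14.57, 14.47],
    "1-Octen-3-one-M": [5.59, 5.09, 5.48, 4.93, 5.13],
    "2-Heptanone-D": [0.10, 0.13, 0.16, 0.17, 0.19],
    "2-Heptanone-M": [0.20, 0.20, 0.25, 0.22, 0.26],
    "2-Hexanone": [0.43, 0.37, 0.42, 0.37, 0.41],
    "2-Methylbutanal-D": [18.88, 16.28, 17.14, 16.57, 17.68],
    "2-Methylbutanal-M": [1.71, 1.20, 1.44, 1.09, 1.23],
    "2-Methylpyrazine": [0.02, 0.01, 0.01, 0.01, 0.01],
    "2-Pentanone": [0.21, 0.20, 0.28, 0.18, 0.23],
    "3-Methylbutanal": [0.30, 0.35, 0.41, 0.45, 0.46],
    "3-Octanol-D": [0.10, 0.07, 0.07, 0.06, 0.06],
    "3-Octanol-M": [0.18, 0.16, 0.17, 0.14, 0.15],
    "3-Octanone-D": [0.06, 0.05, 0.04, 0.04, 0.06],
    "3-Octanone-M": [0.11, 0.09, 0.09, 0.08, 0.10],
    "Ethyl acetate": [0.10, 0.11, 0.13, 0.12, 0.14],
    "Butanal-D": [16.80, 16.12, 18.83, 17.52, 19.58],
    "Butanal-M": [0.43, 0.50, 0.58, 0.63, 0.82],
    "Heptanal": [3.97, 4.08, 3.83, 3.85, 3.83],
    "Methyl isovalerate": [18.92, 17.82, 18.53, 19.47, 21.21],
    "n-Pentanal-D": [5.96, 6.03, 5.92, 6.13, 5.58],
    "n-Pentanal-M": [1.83, 1.63, 1.90, 1.76, 2.10],
}

# cells where the published score table is internally inconsistent with the
# published contents (beyond 2-d.p. rounding); the butanal rows are covered
# by the swap assertion instead
KNOWN_DISCREPANT = {
    ("1-Octen-3-one-M", "D"),
    ("2-Heptanone-M", "C"),
    ("2-Methylbutanal-D", "E"),
}

GROUPS = list("ABCDE")


def _score(roav, name, group):
    stem, form = fl.split_form(name)
    sub = roav.scores.data
    m = sub[(sub.analyte_id == stem) & (sub.form == form)
            & (sub.sample_group == group)]
    return float(m.score.iloc[0])


def test_reference_selection(fx):
    for g in GROUPS:
        assert select_reference(fx.voc_table, fx.voc_thresholds, g) == (
            "1-Octanal", "monomer",
        )


def test_reference_trivial_and_tie():
    db = fl.ThresholdDB(
        pd.DataFrame({"analyte_id": ["B", "A"], "threshold": [1.0, 2.0]}), "odor"
    )
    one = fl.AnalyteTable(
        pd.DataFrame([{"analyte_id": "B", "sample_group": "A", "value": 5.0}]),
        "relative_percent",
    )
    assert select_reference(one, db, "A") == ("B", "none")
    tie = fl.AnalyteTable(
        pd.DataFrame(
            [{"analyte_id": "B", "sample_group": "A", "value": 1.0},
             {"analyte_id": "A", "sample_group": "A", "value": 2.0}]
        ),
        "relative_percent",
    )  # equal content/threshold ratios -> lexicographically first name
    assert select_reference(tie, db, "A") == ("A", "none")


def test_reference_scores_100_everywhere(roav):
    for g in GROUPS:
        assert _score(roav, "1-Octanal-M", g) == 100.0


def test_max_score_is_reference(roav):
    by_group = roav.scores.data.dropna(subset=["score"]).groupby("sample_group")
    assert (by_group.score.max() == 100.0).all()


@pytest.mark.parametrize(
    "name,group,expected", [("(Z)-4-Heptenal", "A", 5.76), ("1-Hexanal-D", "A", 4.21)]
)
def test_worked_examples(roav, name, group, expected):
    assert _score(roav, name, group) == pytest.approx(expected, rel=0.02)


def test_printed_table_reproduced_outside_known_discrepancies(fx, roav):
    wide = fx.voc_table.pivot()
    t_ref = fx.voc_thresholds.threshold_for("1-Octanal")
    mismatches = []
    for name, vals in PRINTED_ROAV.items():
        stem, form = fl.split_form(name)
        if stem == "Butanal":
            continue
        t = fx.voc_thresholds.threshold_for(stem)
        for gi, g in enumerate(GROUPS):
            c = wide.loc[(stem, form), g]
            ref = wide.loc[("1-Octanal", "monomer"), g]
            lo = ((c - 0.005) / (ref + 0.005)) * (t_ref / t) * 100 - 0.005
            hi = ((c + 0.005) / (ref - 0.005)) * (t_ref / t) * 100 + 0.005
            if not lo <= vals[gi] <= hi:
                mismatches.append((name, g))
    assert set(mismatches) == KNOWN_DISCREPANT


def test_butanal_rows_are_swapped(roav):
    for gi, g in enumerate(GROUPS):
        printed_d = PRINTED_ROAV["Butanal-D"][gi]
        # the published dimer score is reproducible only from the published
        # *monomer* content — swapped labels in one of the two source tables
        assert _score(roav, "Butanal-M", g) == pytest.approx(printed_d, rel=0.02)
        # while the score computed from the dimer content stays sub-key
        assert _score(roav, "Butanal-D", g) < 1.0 < printed_d


def test_key_and_modifier_screening(roav):
    assert roav.key_compounds == [
        "(Z)-4-Heptenal", "1-Hexanal", "1-Nonanal", "1-Octanal", "1-Octen-3-ol",
        "1-Octen-3-one", "2-Methylbutanal", "Butanal", "Heptanal",
        "Methyl isovalerate", "n-Pentanal",
    ]
    assert len(roav.key_compounds) == 11
    assert roav.modifier_compounds == [
        "2-Heptanone", "2-Hexanone", "2-Pentanone", "3-Methylbutanal",
        "3-Octanol", "3-Octanone", "Ethyl acetate",
    ]


def test_per_form_screening(roav):
    keys, _ = screen_roav(roav, merge_forms=False)
    # the butanal dimer signal alone stays below the key cut; merged
    # screening is what recovers the compound
    assert "Butanal-M" in keys and "Butanal-D" not in keys


def test_boundary_is_inclusive():
    table = fl.AnalyteTable(
        pd.DataFrame(
            [{"analyte_id": "R", "sample_group": "A", "value": 50.0},
             {"analyte_id": "K", "sample_group": "A", "value": 0.5}]
        ),
        "relative_percent",
    )
    db = fl.ThresholdDB(
        pd.DataFrame({"analyte_id": ["R", "K"], "threshold": [1.0, 1.0]}), "odor"
    )
    res = compute_roav(table, db)  # K scores exactly (0.5/50)*100 = 1.0
    assert _score(res, "K", "A") == 1.0
    assert res.key_compounds == ["K", "R"]


def test_all_below_modifier_cut_gives_empty_lists(roav):
    keys, mods = screen_roav(roav, key_cut=1e6, modifier_cut=1e5)
    assert keys == [] and mods == []


def test_scale_invariance(fx, roav):
    scaled = fl.AnalyteTable(
        fx.voc_table.data.assign(value=fx.voc_table.data.value * 7.5),
        "relative_percent",
    )
    res = compute_roav(scaled, fx.voc_thresholds)
    a = roav.scores.data.sort_values(["analyte_id", "form", "sample_group"]).score
    b = res.scores.data.sort_values(["analyte_id", "form", "sample_group"]).score
    assert np.allclose(a.to_numpy(), b.to_numpy(), rtol=1e-12, equal_nan=True)


def test_missing_threshold_compounds_excluded(fx, roav):
    excl = roav.scores.data[roav.scores.data.classification
                            == "excluded_no_threshold"]
    assert set(excl.analyte_id) == set(fx.voc_thresholds.missing)
    assert excl.score.isna().all()


def test_fixed_reference_must_exist(fx):
    with pytest.raises(fl.ValidationError, match="Nonexistent"):
        compute_roav(fx.voc_table, fx.voc_thresholds, reference="Nonexistent-M")
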