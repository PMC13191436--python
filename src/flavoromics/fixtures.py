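"""Packaged study tables for the five-cooking-time mushroom-soup experiment.

The fixtures carry the published group-mean +/- SD tables for *Sarcodon
imbricatus* soup cooked for 30/60/90/120/150 min (sample groups A-E):

* 17 free amino acids (mg/kg) with taste thresholds and taste-class tags
  (Arg's threshold is not published; 500 mg/kg is back-calculated from its
  published contents and activity values and flagged in the data file);
* 5 flavor 5'-nucleotides (mg/kg), no thresholds published;
* 50 GC-IMS volatile signals (relative content %, monomer/dimer resolved)
  plus the unidentified-peak remainder carried as the pseudo-analyte
  ``Others`` so per-sample contents close to 100%;
* odor thresholds in water (mg/kg) with odor descriptors for the 26
  compounds that have one, and explicit missing-threshold records for the
  remaining 11;
* a chemical-class map (aldehyde/ketone/alcohol/ester/ether/olefin/
  heterocyclic) for the 37 unique compounds.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from .core import AnalyteTable, ThresholdDB, canonical_name
from .io import read_analyte_table, read_threshold_db

__all__ = ["StudyFixtures", "load_fixtures", "fixture_path"]


def fixture_path(name: str):
    """Filesystem path of a packaged fixture CSV (also consumable as plain CSV)."""
    return resources.files(__package__) / "data" / name


@dataclass
class StudyFixtures:
    """The full set of packaged study tables."""

    faa_table: AnalyteTable
    faa_thresholds: ThresholdDB
    nucleotide_table: AnalyteTable
    voc_table: AnalyteTable
    voc_others: AnalyteTable
    voc_thresholds: ThresholdDB
    voc_class_map: dict[str, str]

    def voc_with_others(self) -> AnalyteTable:
        """VOC table including the unidentified-peak remainder.

        With ``Others`` included the per-sample relative contents sum to
        ~100%, which is what the class-aggregation closure checks use.
        """
        import pandas as pd

        return AnalyteTable(
            pd.concat([self.voc_table.data, self.voc_others.data], ignore_index=True),
            "relative_percent",
        )


def load_fixtures() -> StudyFixtures:
    """Load the packaged study tables.

    The tables round-trip losslessly through :mod:`flavoromics.io`.
    """
    faa = read_analyte_table(fixture_path("faa_concentrations.csv"),
                             "concentration_mg_per_kg")
    faa_thr = read_threshold_db(fixture_path("faa_taste_thresholds.csv"), "taste")
    nuc = read_analyte_table(fixture_path("nucleotide_concentrations.csv"),
                             "concentration_mg_per_kg")
    voc = read_analyte_table(fixture_path("voc_relative_content.csv"),
                             "relative_percent")
    others = read_analyte_table(fixture_path("voc_unidentified.csv"),
                                "relative_percent")
    voc_thr = read_threshold_db(fixture_path("voc_odor_thresholds.csv"), "odor")
    import pandas as pd

    cls = pd.read_csv(fixture_path("voc_classes.csv"))
    class_map = {
        canonical_name(a): c for a, c in zip(cls["analyte"], cls["chemical_class"])
    }
    return StudyFixtures(
        faa_table=faa,
        faa_thresholds=faa_thr,
        nucleotide_table=nuc,
        voc_table=voc,
        voc_others=others,
        voc_thresholds=voc_thr,
        voc_class_map=class_map,
    )
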