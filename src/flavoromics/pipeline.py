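"""End-to-end orchestration of the flavoromics inference chain.

``run_pipeline`` drives the full analysis:

1. load the packaged study tables (or user-supplied CSVs);
2. TAV scoring of amino acids / nucleotides with key/modifier lists;
3. ROAV scoring of the volatile table with key-odorant screening;
4. OPLS-DA (+ VIP, + label-permutation validation) on replicate-level
   data — simulated around the group means, because only means are
   published — restricted to the ROAV-screened key compounds;
5. a Pearson correlation panel of the VIP-selected volatiles against the
   key amino acids and the nucleotides on the five group means;
6. a JSON run manifest recording seeds, cut-offs, data provenance and
   per-stage status, so a synthetic-replicate result can never be mistaken
   for a published-replicate one.

Every output is a CSV table or JSON document; the whole bundle is a
deterministic function of (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import AnalyteTable, ValidationError, canonical_name
from .fixtures import load_fixtures
from .io import read_analyte_table, read_threshold_db, write_score_table
from .multivariate import fit_oplsda, permutation_test, to_matrix, vip
from .odor import compute_roav
from .synthetic import SimulationConfig, simulate_replicates
from .taste import aggregate_taste_classes, tav_table

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "simulate"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the manifest records which."""


@dataclass
class PipelineConfig:
    """Inputs, cut-offs and model settings for one pipeline run.

    Paths set to ``"fixtures"`` use the packaged study tables.  The cuts
    default to the conventional activity-value thresholds (key at 1.0,
    modifier at 0.1, VIP at 1.0).
    """

    faa_table: str = "fixtures"
    faa_thresholds: str = "fixtures"
    nucleotide_table: str = "fixtures"
    voc_table: str = "fixtures"
    voc_thresholds: str = "fixtures"
    tav_key_cut: float = 1.0
    tav_mod_cut: float = 0.1
    roav_key_cut: float = 1.0
    roav_mod_cut: float = 0.1
    vip_cut: float = 1.0
    merge_forms: bool = True
    n_replicates: int = 3
    scaling: str = "unit_variance"
    cv_folds: int = 7
    n_orthogonal: int = 1
    n_permutations: int = 200
    seed: int = 0
    output_dir: str = "flavoromics_out"

    def __post_init__(self) -> None:
        for name in ("tav_key_cut", "tav_mod_cut", "roav_key_cut",
                     "roav_mod_cut", "vip_cut"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.tav_mod_cut >= self.tav_key_cut:
            raise ValidationError("tav_mod_cut must be below tav_key_cut")
        if self.roav_mod_cut >= self.roav_key_cut:
            raise ValidationError("roav_mod_cut must be below roav_key_cut")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))


def _load_inputs(config: PipelineConfig):
    fx = load_fixtures() if "fixtures" in (
        config.faa_table, config.faa_thresholds, config.nucleotide_table,
        config.voc_table, config.voc_thresholds,
    ) else None

    def table(attr, kind, fixture):
        p = getattr(config, attr)
        return fixture if p == "fixtures" else read_analyte_table(p, kind)

    faa = table("faa_table", "concentration_mg_per_kg", fx and fx.faa_table)
    nuc = table("nucleotide_table", "concentration_mg_per_kg",
                fx and fx.nucleotide_table)
    voc = table("voc_table", "relative_percent", fx and fx.voc_table)
    faa_thr = (fx.faa_thresholds if config.faa_thresholds == "fixtures"
               else read_threshold_db(config.faa_thresholds, "taste"))
    voc_thr = (fx.voc_thresholds if config.voc_thresholds == "fixtures"
               else read_threshold_db(config.voc_thresholds, "odor"))
    voc_full = fx.voc_with_others() if fx and config.voc_table == "fixtures" else voc
    return faa, faa_thr, nuc, voc, voc_thr, voc_full


def simulate(config: SimulationConfig, output_dir) -> Path:
    """Write a simulated replicate-level dataset ready for the pipeline."""
    from .io import write_analyte_table

    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = simulate_replicates(config)
    write_analyte_table(table, out / "simulated_replicates.csv")
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the whole chain; returns the manifest dict.

    Outputs are written under ``config.output_dir``.  On a stage failure
    partial outputs are retained, the manifest carries a FAILED marker for
    the stage, and :class:`PipelineError` is raised.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "cuts": {
            "tav_key": config.tav_key_cut, "tav_mod": config.tav_mod_cut,
            "roav_key": config.roav_key_cut, "roav_mod": config.roav_mod_cut,
            "vip": config.vip_cut,
        },
        "merge_forms": config.merge_forms,
        "multivariate": {
            "scaling": config.scaling, "cv_folds": config.cv_folds,
            "n_orthogonal": config.n_orthogonal,
            "n_permutations": config.n_permutations,
            "n_replicates": config.n_replicates,
            "data_provenance": "simulated-replicates-around-group-means",
        },
        "stages": {},
        "excluded_analytes": {},
    }
    stage = "load_inputs"
    try:
        faa, faa_thr, nuc, voc, voc_thr, voc_full = _load_inputs(config)
        manifest["stages"][stage] = "ok"

        stage = "taste_scoring"
        tav = tav_table(faa, faa_thr, config.tav_key_cut, config.tav_mod_cut)
        write_score_table(tav, out / "tav_scores.csv")
        aggregate_taste_classes(faa, faa_thr).to_csv(out / "taste_class_totals.csv")
        nuc_tav = tav_table(nuc, faa_thr, config.tav_key_cut, config.tav_mod_cut)
        write_score_table(nuc_tav, out / "nucleotide_tav_scores.csv")
        manifest["key_taste_compounds"] = tav.extra["key_compounds"]
        manifest["modifier_taste_compounds"] = tav.extra["modifier_compounds"]
        manifest["excluded_analytes"]["taste"] = [
            f"{a}: no taste threshold" for a in sorted(
                set(tav.data.loc[tav.data.classification ==
                                 "excluded_no_threshold", "analyte_id"])
            )
        ]
        manifest["stages"][stage] = "ok"

        stage = "odor_scoring"
        roav = compute_roav(
            voc, voc_thr, key_cut=config.roav_key_cut,
            modifier_cut=config.roav_mod_cut, merge_forms=config.merge_forms,
        )
        write_score_table(roav.scores, out / "roav_scores.csv")
        manifest["roav_reference"] = {
            g: roav.reference_name(g) for g in roav.references
        }
        manifest["key_odor_compounds"] = roav.key_compounds
        manifest["modifier_odor_compounds"] = roav.modifier_compounds
        manifest["excluded_analytes"]["odor"] = [
            f"{a}: no odor threshold" for a in sorted(
                set(roav.scores.data.loc[
                    roav.scores.data.classification == "excluded_no_threshold",
                    "analyte_id"])
            )
        ]
        manifest["stages"][stage] = "ok"

        stage = "multivariate"
        key_stems = {canonical_name(c) for c in roav.key_compounds}
        if not key_stems:
            raise PipelineError(
                "empty variable set: no compound passes roav_key_cut "
                f"{config.roav_key_cut}"
            )
        sim = simulate_replicates(SimulationConfig(
            means=voc_full, n_replicates=config.n_replicates, seed=config.seed,
        ))
        sim_key = sim.subset(
            [a for a in sim.data["analyte_id"].unique()
             if canonical_name(a) in key_stems]
        )
        X, y = to_matrix(sim_key)
        # stratified CV cannot use more folds than the smallest group has
        # replicates; cap and record the effective fold count
        counts = pd.Series(y).value_counts()
        folds = int(min(config.cv_folds, counts.min()))
        manifest["multivariate"]["cv_folds_effective"] = folds
        model = fit_oplsda(
            X, y, n_orthogonal=config.n_orthogonal, cv_folds=folds,
            seed=config.seed, scaling=config.scaling,
        )
        vips = vip(model).sort_values(ascending=False)
        vips.rename_axis("variable").to_csv(out / "vip_table.csv")
        model.to_json(out / "oplsda_model.json")
        perm = permutation_test(
            X, y, n_permutations=config.n_permutations, seed=config.seed,
            n_orthogonal=config.n_orthogonal, cv_folds=folds,
            scaling=config.scaling,
        )
        manifest["oplsda"] = {
            "n_variables": int(X.shape[1]),
            "n_observations": int(X.shape[0]),
            "R2X": round(model.r2x, 6),
            "R2Y": round(model.r2y, 6),
            "Q2": round(model.q2, 6),
            "permutation": {
                "n": perm.n_permutations,
                "q2_perm_median": round(float(np.median(perm.q2_perm)), 6),
                "q2_perm_p95": round(float(np.quantile(perm.q2_perm, 0.95)), 6),
                "r2y_intercept": round(perm.r2y_intercept, 6),
                "q2_intercept": round(perm.q2_intercept, 6),
            },
        }
        vip_selected = sorted(vips.index[vips > config.vip_cut])
        manifest["vip_selected"] = vip_selected
        manifest["stages"][stage] = "ok"

        stage = "correlation"
        from .correlate import pearson_matrix

        taste_vars = tav.extra["key_compounds"]
        taste_means = pd.concat(
            [faa.subset(taste_vars).pivot(), nuc.pivot()]
        ).droplevel("form").T
        from .core import display_name

        odor_means = voc.pivot().T
        odor_means.columns = [display_name(a, f) for a, f in odor_means.columns]
        odor_means = odor_means.reindex(taste_means.index)
        panel_cols = [c for c in odor_means.columns if c in set(vip_selected)]
        corr = pearson_matrix(taste_means, odor_means[panel_cols])
        corr.pairs.to_csv(out / "correlation_panel.csv", index=False)
        manifest["stages"][stage] = "ok"
    except Exception as exc:
        manifest["stages"][stage] = f"FAILED: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
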