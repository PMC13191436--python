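"""Replicate-level synthetic data with the structure the analysis assumes.

The study publishes only group means +/- SD (five cooking-time groups, three
analytical replicates behind each printed mean).  The generator reproduces
that structure: per (analyte, form, group) cell it draws ``n_replicates``
values from a Normal(mean, SD) truncated at zero — concentrations and
relative contents cannot be negative, and mean +/- SD reporting is what a
truncated Gaussian emulates most directly.  Relative-content tables are
re-normalized per replicate so each simulated sample again sums to 100%
(semi-quantification); for the configured means to be recovered the
template must therefore describe the full composition (include the
unidentified remainder).

Replicates are drawn independently; real batch effects or inter-replicate
correlation are not emulated.  A *discrimination injection* helper shifts
selected analytes' group means monotonically across the group order to
create ground-truth discriminating variables for model-recovery tests, and
an electronic-nose generator emulates sensor-array response tables with
five parallel repeats per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import AnalyteTable, ValidationError, canonical_name

__all__ = [
    "SimulationConfig",
    "simulate_replicates",
    "simulate_enose",
    "inject_discrimination",
    "default_enose_profile",
]

ENOSE_REPEATS = 5  # parallel e-nose experiments per sample


@dataclass
class SimulationConfig:
    """Configuration for replicate-level simulation.

    ``means`` is a template :class:`AnalyteTable` whose ``value`` column
    holds the per-cell mean and whose ``sd`` column holds the per-cell SD
    (every mean must have an SD).  ``n_replicates`` defaults to 3,
    the standard analytical-triplicate practice behind mean +/- SD tables.
    """

    means: AnalyteTable
    n_replicates: int = 3
    seed: int = 0
    noise_model: str = "gaussian_truncated_at_zero"
    renormalize: bool | None = None  # None -> auto for relative_percent tables
    discriminating_set: list[str] | None = None
    enose_profile: pd.DataFrame | None = None  # sensors x groups mean responses
    enose_relative_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValidationError(
                "n_replicates must be >= 2 so within-group variance is estimable"
            )
        if self.noise_model != "gaussian_truncated_at_zero":
            raise ValidationError(f"unknown noise model {self.noise_model!r}")
        if self.means.data["sd"].isna().any():
            missing = self.means.data.loc[
                self.means.data["sd"].isna(), "analyte_id"
            ].iloc[0]
            raise ValidationError(f"mean without SD for analyte {missing!r}")

    @property
    def do_renormalize(self) -> bool:
        if self.renormalize is None:
            return self.means.value_kind == "relative_percent"
        return self.renormalize


def _truncated_normal(rng, mean: np.ndarray, sd: np.ndarray, size) -> np.ndarray:
    """Normal(mean, sd) truncated at zero; degenerate sd=0 yields the mean."""
    out = np.broadcast_to(mean, size).astype(float).copy()
    pos = np.broadcast_to(sd, size) > 0
    if pos.any():
        m, s = np.broadcast_to(mean, size)[pos], np.broadcast_to(sd, size)[pos]
        a = (0.0 - m) / s  # lower bound in standard units
        out[pos] = stats.truncnorm.rvs(
            a, np.inf, loc=m, scale=s, size=int(pos.sum()), random_state=rng
        )
    return out


def simulate_replicates(config: SimulationConfig) -> AnalyteTable:
    """Draw ``n_replicates`` values per (analyte, form, group) cell.

    Identical config and seed give identical output; no negative value is
    ever emitted.
    """
    rng = np.random.default_rng(config.seed)
    base = config.means.data
    n = config.n_replicates
    draws = _truncated_normal(
        rng,
        base["value"].to_numpy()[:, None],
        base["sd"].to_numpy()[:, None],
        (len(base), n),
    )
    rows = base.loc[base.index.repeat(n)].reset_index(drop=True)
    rows["replicate"] = np.tile(np.arange(1, n + 1), len(base))
    rows["value"] = draws.reshape(-1)
    rows["sd"] = np.nan
    out = AnalyteTable(rows, config.means.value_kind)
    if config.do_renormalize:
        from .peaks import normalize_to_relative_content

        out = normalize_to_relative_content(out)
    return out


def inject_discrimination(
    table: AnalyteTable, ids: list[str], shift: float
) -> AnalyteTable:
    """Give listed analytes a monotone between-group shift of known size.

    The *j*-th listed analyte is raised by ``shift`` pooled within-group
    SDs in every group at or beyond breakpoint ``1 + (j mod (G-1))`` of the
    group order — a monotone step whose position cycles through the group
    gaps.  Distinct breakpoints make a listed *set* span the between-group
    contrast space (each compound switches at a different cooking stage),
    which is what gives model-recovery experiments an identifiable ground
    truth; a single listed analyte separates the first group from the rest.

    The pooled SD is estimated from the table's replicates.  Other analytes
    are untouched; ``shift = 0`` is the identity; values are clipped at
    zero.
    """
    df = table.data.copy()
    known = set(df["analyte_id"].map(canonical_name))
    order = []
    for a in ids:
        key = canonical_name(a)
        if key not in known:
            raise ValidationError(f"unknown analyte {a!r}")
        order.append(key)
    breakpoints = {a: 1 + (j % (len(table.groups) - 1)) for j, a in enumerate(order)}
    group_rank = {g: k for k, g in enumerate(table.groups)}
    stems = df["analyte_id"].map(canonical_name)
    for (stem, _form), sub in df.groupby([stems, df["form"]], sort=False):
        if stem not in breakpoints:
            continue
        resid = sub["value"] - sub.groupby(sub["sample_group"])["value"].transform("mean")
        dof = len(sub) - sub["sample_group"].nunique()
        sd = float(np.sqrt((resid**2).sum() / dof)) if dof > 0 else 0.0
        if sd == 0.0:
            sd = max(abs(sub["value"].mean()) * 0.05, 1e-12)
        step = sub["sample_group"].map(group_rank).to_numpy() >= breakpoints[stem]
        df.loc[sub.index, "value"] = np.clip(
            sub["value"].to_numpy() + step * shift * sd, 0.0, None
        )
    return AnalyteTable(df, table.value_kind)


def default_enose_profile() -> pd.DataFrame:
    """A realistic 10-sensor array profile for the five cooking times.

    Sensors S2 (carbon-containing compounds), S3 (hydrogen) and S6
    (aldehydes/ketones) respond consistently higher than the rest, and the
    total response peaks in group D — the qualitative pattern an e-nose
    shows on this soup.  Units are relative response ratios.
    """
    groups = ["A", "B", "C", "D", "E"]
    base = {
        "S1": 1.20, "S2": 2.80, "S3": 2.40, "S4": 1.10, "S5": 1.30,
        "S6": 3.00, "S7": 1.00, "S8": 1.10, "S9": 1.40, "S10": 1.20,
    }
    scale = {"A": 0.95, "B": 1.00, "C": 1.05, "D": 1.15, "E": 1.08}
    # mild sensor-specific trends so groups separate in sensor space
    trend = {
        "S2": {"A": 0.10, "B": 0.05, "C": 0.00, "D": -0.05, "E": -0.10},
        "S6": {"A": -0.15, "B": -0.05, "C": 0.05, "D": 0.20, "E": 0.10},
        "S9": {"A": -0.05, "B": 0.00, "C": 0.05, "D": 0.05, "E": 0.10},
    }
    prof = pd.DataFrame(
        {g: {s: base[s] * scale[g] + trend.get(s, {}).get(g, 0.0) for s in base}
         for g in groups}
    )
    prof.index.name = "sensor"
    return prof


def simulate_enose(config: SimulationConfig) -> AnalyteTable:
    """Sensor-response table with five parallel repeats per sample group.

    Sensors play the role of analytes; responses are truncated-Gaussian
    around the profile means with a relative SD of
    ``config.enose_relative_sd``.  Group structure is recoverable by PCA.
    """
    if config.enose_profile is None:
        raise ValidationError("enose_profile missing from config")
    prof = config.enose_profile
    rng = np.random.default_rng(config.seed)
    rows = []
    for g in prof.columns:
        means = prof[g].to_numpy(float)
        sds = np.abs(means) * config.enose_relative_sd
        draws = _truncated_normal(rng, means[:, None], sds[:, None],
                                  (len(means), ENOSE_REPEATS))
        for i, sensor in enumerate(prof.index):
            for r in range(ENOSE_REPEATS):
                rows.append(
                    {"analyte_id": sensor, "sample_group": str(g),
                     "replicate": r + 1, "value": draws[i, r]}
                )
    return AnalyteTable(pd.DataFrame(rows), "relative_percent")
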