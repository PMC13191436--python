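"""Taste-odor Pearson correlation screening and hierarchical clustering.

Correlations are computed pairwise between a panel of taste variables
(amino acids, nucleotides) and a panel of odor variables (volatile
signals) over matched observations — by default the five cooking-time
group means, since only means are published.  Two-sided p-values come from
the t-distribution with n-2 degrees of freedom; stars are applied at the
conventional 0.05 / 0.01 levels with no multiple-testing correction (a
Benjamini-Hochberg option is available but off by default, mirroring
raw-p-value star conventions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .core import ValidationError

__all__ = [
    "CorrelationResult",
    "ClusterLayout",
    "pearson_matrix",
    "hierarchical_cluster",
    "zscore_rows",
]


@dataclass
class CorrelationResult:
    """Long-format pairwise correlations with significance flags."""

    pairs: pd.DataFrame  # columns: var_a, var_b, r, p, n, flag

    def r_matrix(self) -> pd.DataFrame:
        return self.pairs.pivot(index="var_a", columns="var_b", values="r")

    def get(self, var_a: str, var_b: str) -> pd.Series:
        m = self.pairs[(self.pairs.var_a == var_a) & (self.pairs.var_b == var_b)]
        if m.empty:
            raise KeyError((var_a, var_b))
        return m.iloc[0]


def _flag(p: float) -> str:
    if p < 0.01:
        return "highly_significant"
    if p < 0.05:
        return "significant"
    return "ns"


def pearson_matrix(
    A: pd.DataFrame, B: pd.DataFrame, bh_correct: bool = False
) -> CorrelationResult:
    """All pairwise Pearson r / two-sided p between columns of A and B.

    A and B must share their observation index (n >= 3).  Zero-variance
    variables cannot be correlated; their pairs are reported with flag
    ``excluded`` and NaN r/p rather than dropped silently.  With
    ``bh_correct`` the p-values are Benjamini-Hochberg adjusted before
    flagging.
    """
    if len(A) != len(B) or not A.index.equals(B.index):
        raise ValidationError("A and B must have matched observations")
    n = len(A)
    if n < 3:
        raise ValidationError("need at least 3 observations for a p-value")
    rows = []
    for a in A.columns:
        x = A[a].to_numpy(float)
        for b in B.columns:
            y = B[b].to_numpy(float)
            if np.std(x) == 0 or np.std(y) == 0:
                rows.append(
                    {"var_a": a, "var_b": b, "r": np.nan, "p": np.nan,
                     "n": n, "flag": "excluded"}
                )
                continue
            r, p = stats.pearsonr(x, y)
            rows.append({"var_a": a, "var_b": b, "r": r, "p": p, "n": n, "flag": ""})
    df = pd.DataFrame(rows)
    ok = df["flag"] != "excluded"
    pvals = df.loc[ok, "p"].to_numpy()
    if bh_correct and len(pvals):
        pvals = _benjamini_hochberg(pvals)
        df.loc[ok, "p"] = pvals
    df.loc[ok, "flag"] = [_flag(p) for p in df.loc[ok, "p"]]
    return CorrelationResult(df)


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank, idx in list(enumerate(order, start=1))[::-1]:
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


@dataclass
class ClusterLayout:
    """Agglomerative clustering of matrix rows."""

    labels: list[str]
    order: list[int]         # leaf order (left-to-right traversal)
    linkage: np.ndarray      # scipy linkage matrix (merge heights ascending)
    metric: str
    method: str

    @property
    def ordered_labels(self) -> list[str]:
        return [self.labels[i] for i in self.order]

    def merge_height(self, label_a: str, label_b: str) -> float:
        """Height at which two leaves first share a cluster."""
        ia, ib = self.labels.index(label_a), self.labels.index(label_b)
        n = len(self.labels)
        members = {i: {i} for i in range(n)}
        for k, (l, r, h, _) in enumerate(self.linkage):
            merged = members.pop(int(l)) | members.pop(int(r))
            if ia in merged and ib in merged:
                return float(h)
            members[n + k] = merged
        raise KeyError((label_a, label_b))

    def newick(self) -> str:
        """Bracketed tree text with branch lengths from merge heights."""
        tree = hierarchy.to_tree(self.linkage)

        def fmt(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            inner = ",".join(fmt(c, node.dist) for c in (node.left, node.right))
            return f"({inner}):{length:.6g}"

        inner = ",".join(fmt(c, tree.dist) for c in (tree.left, tree.right))
        return f"({inner});"


def hierarchical_cluster(
    M: pd.DataFrame, metric: str = "euclidean", method: str = "average"
) -> ClusterLayout:
    """Deterministic agglomerative clustering of the rows of M.

    ``metric`` is ``euclidean`` or ``correlation``; ``method`` one of
    ``average``/``ward``/``complete`` (ward requires euclidean).  Leaf
    order is the standard recursive left-to-right dendrogram traversal.
    """
    if metric not in ("euclidean", "correlation"):
        raise ValidationError(f"unknown metric {metric!r}")
    if method not in ("average", "ward", "complete"):
        raise ValidationError(f"unknown linkage {method!r}")
    if method == "ward" and metric != "euclidean":
        raise ValidationError("ward linkage requires euclidean distances")
    X = M.to_numpy(float)
    if len(X) < 2:
        raise ValidationError("need at least 2 rows to cluster")
    if np.isnan(X).any():
        raise ValidationError("NaN in matrix")
    Z = hierarchy.linkage(pdist(X, metric=metric), method=method)
    order = hierarchy.leaves_list(Z)
    return ClusterLayout(
        labels=[str(l) for l in M.index],
        order=[int(i) for i in order],
        linkage=Z,
        metric=metric,
        method=method,
    )


def zscore_rows(M: pd.DataFrame) -> pd.DataFrame:
    """Standardize each row to mean 0, SD 1 (population convention).

    Standard heatmap preprocessing; a constant row cannot be standardized
    and raises an error naming the row.
    """
    X = M.to_numpy(float)
    sd = X.std(axis=1, ddof=0)
    flat = np.flatnonzero(sd == 0)
    if len(flat):
        raise ValidationError(f"constant row {M.index[flat[0]]!r}: cannot z-score")
    Z = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    return pd.DataFrame(Z, index=M.index, columns=M.columns)
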