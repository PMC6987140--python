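"""Descriptive surfaces: severity-quantile profiles, heatmaps, summaries.

Every variable is mapped to its pooled empirical severity quantile —
0 is the healthiest observed state and 1 the most severe, with the
catalog's direction deciding which end is which — so cluster medians of
very different variables share one comparable [0, 1] axis.  Median
uncertainty uses the distribution-free order-statistic interval from the
Binomial(n, 1/2) distribution.  Variables are ordered by average-linkage
clustering of their cluster-median profiles so similar patterns sit next
to each other, and the signed pairwise calls become a three-state heatmap
with average-linkage dendrogram orderings on both axes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .cohort import Cohort
from .signatures import SignatureTable
from .stats import kruskal_wallis


def empirical_quantile_transform(values, direction: str = "higher_worse"
                                 ) -> np.ndarray:
    """Pooled severity quantiles in [0, 1] via (midrank - 1) / (n - 1).

    The observed minimum maps to 0 and the maximum to 1; ties share their
    midrank quantile.  ``higher_better`` variables are flipped so 1 is
    always the most severe state.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 values")
    if direction not in ("higher_worse", "higher_better"):
        raise ValueError(f"bad direction {direction!r}")
    if np.ptp(x) == 0:
        warnings.warn("constant variable: all quantiles set to 0.5")
        return np.full(len(x), 0.5)
    q = (sps.rankdata(x) - 1.0) / (len(x) - 1.0)
    return 1.0 - q if direction == "higher_better" else q


class MedianCI(NamedTuple):
    median: float
    lower: float
    upper: float
    degenerate: bool


def median_with_binomial_ci(values, level: float = 0.95) -> MedianCI:
    """Sample median with the order-statistic CI from Binomial(n, 1/2).

    lower = x_(l) with l the largest integer whose Binomial CDF at l-1 is
    <= (1-level)/2; upper = x_(u) with u the smallest integer whose CDF at
    u-1 is >= 1-(1-level)/2.  When n is too small for the level the full
    observed range is returned with the degenerate flag set.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if n == 0:
        raise ValueError("empty vector")
    med = float(np.median(x))
    alpha = (1.0 - level) / 2.0
    cdf = sps.binom.cdf(np.arange(n + 1), n, 0.5)   # cdf[i] = P(X <= i)
    lo_ok = np.flatnonzero(cdf[:-1] <= alpha)        # candidates l-1
    hi_ok = np.flatnonzero(cdf[:-1] >= 1.0 - alpha)  # candidates u-1
    if len(lo_ok) == 0 or len(hi_ok) == 0:
        return MedianCI(med, float(x[0]), float(x[-1]), True)
    l = int(lo_ok[-1]) + 1
    u = int(hi_ok[0]) + 1
    return MedianCI(med, float(x[l - 1]), float(x[u - 1]), False)


@dataclass
class QuantileProfile:
    """Per-cluster median severity quantiles with binomial CIs.

    ``medians``/``lower``/``upper`` are clusters x variables frames in
    [0, 1]; ``order`` is the similarity ordering of the variables.
    """

    medians: pd.DataFrame
    lower: pd.DataFrame
    upper: pd.DataFrame
    order: list[str]
    level: float = 0.95

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.medians.index:
            for v in self.medians.columns:
                rows.append({"cluster": c, "variable": v,
                             "median_q": self.medians.loc[c, v],
                             "lower": self.lower.loc[c, v],
                             "upper": self.upper.loc[c, v]})
        return pd.DataFrame(rows)


def _canonical_leaf_order(Z: np.ndarray, keys: list[tuple]) -> list[int]:
    """Dendrogram leaf order with child orientation by smallest leaf key.

    Orientation depends only on leaf data, so the ordering is invariant
    (up to total reflection handled by the root rule) under input
    permutation.
    """
    n = len(keys)
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    minkey: dict[int, tuple] = {i: keys[i] for i in range(n)}
    for i, (a, b, _, _) in enumerate(Z):
        a, b = int(a), int(b)
        first, second = (a, b) if minkey[a] <= minkey[b] else (b, a)
        members[n + i] = members[first] + members[second]
        minkey[n + i] = min(minkey[a], minkey[b])
    return members[n + len(Z) - 1]


def order_variables_by_similarity(profile: pd.DataFrame) -> list[str]:
    """Order variables so similar cluster-median patterns are adjacent.

    Average-linkage hierarchical clustering on Euclidean distance between
    the variables' median-profile vectors; returns the dendrogram leaf
    order with data-driven orientation tie-breaking.
    """
    variables = list(profile.columns)
    if len(variables) < 2:
        return variables
    X = profile.T.to_numpy(dtype=float)
    Z = hierarchy.linkage(X, method="average", metric="euclidean")
    keys = [tuple(np.round(row, 12)) for row in X]
    return [variables[i] for i in _canonical_leaf_order(Z, keys)]


def cluster_quantile_profile(cohort: Cohort, labels: pd.Series,
                             variables: list[str] | None = None,
                             level: float = 0.95) -> QuantileProfile:
    """Quantile profile of the given variables across the label clusters.

    Variables with catalog direction ``none`` are excluded with a warning
    (their severity orientation is undefined).
    """
    catalog = cohort.catalog
    if variables is None:
        variables = catalog.names("CM")
    usable, skipped = [], []
    for v in variables:
        (skipped if catalog.direction(v) == "none" else usable).append(v)
    if skipped:
        warnings.warn(f"excluding direction-less variables: {skipped}")
    clusters = sorted(labels.unique())
    med = pd.DataFrame(index=clusters, columns=usable, dtype=float)
    lo = med.copy()
    hi = med.copy()
    for v in usable:
        q = empirical_quantile_transform(cohort.data[v].to_numpy(),
                                         catalog.direction(v))
        qs = pd.Series(q, index=cohort.data.index)
        for c in clusters:
            ci = median_with_binomial_ci(qs[labels == c].to_numpy(), level)
            med.loc[c, v], lo.loc[c, v], hi.loc[c, v] = ci.median, ci.lower, ci.upper
    order = order_variables_by_similarity(med)
    return QuantileProfile(medians=med, lower=lo, upper=hi, order=order,
                           level=level)


@dataclass
class HeatmapMatrix:
    """Three-state matrix of signed pairwise calls.

    Rows are the pBMs with at least one nonzero call; columns are the
    k(k-1)/2 cluster pairs labelled "a-b"; cells are -1/0/+1 (+1 = the
    first cluster of the pair sits significantly higher by mean rank).
    """

    matrix: pd.DataFrame
    row_order: list[str]
    col_order: list[str]

    def ordered(self) -> pd.DataFrame:
        return self.matrix.loc[self.row_order, self.col_order]


def _hamming_order(M: np.ndarray, names: list[str]) -> list[str]:
    if len(names) < 2:
        return list(names)
    if len(np.unique(M, axis=0)) == 1:
        return list(names)
    Z = hierarchy.linkage(pdist(M, metric="hamming"), method="average")
    keys = [tuple(row) for row in M]
    return [names[i] for i in _canonical_leaf_order(Z, keys)]


def build_heatmap_matrix(table: SignatureTable) -> HeatmapMatrix:
    """Assemble the three-state pairwise heatmap from a signature table."""
    cols = [f"{a}-{b}" for a, b in combinations(table.clusters, 2)]
    sig = table.pairs[table.pairs["sign"] != 0]
    rows = sorted(sig["pbm"].unique())
    M = pd.DataFrame(0, index=pd.Index(rows, name="pbm"), columns=cols,
                     dtype=int)
    for _, r in table.pairs.iterrows():
        if r["pbm"] in M.index:
            M.loc[r["pbm"], f"{r['cluster_a']}-{r['cluster_b']}"] = int(r["sign"])
    row_order = _hamming_order(M.to_numpy(), rows)
    col_order = _hamming_order(M.to_numpy().T, cols)
    return HeatmapMatrix(matrix=M, row_order=row_order, col_order=col_order)


def characterize_clusters(cohort: Cohort, labels: pd.Series,
                          variables: list[str] | None = None) -> pd.DataFrame:
    """Per-cluster descriptive table with across-cluster tests.

    Continuous/ordinal variables get mean (sd) and a Kruskal-Wallis p;
    categorical variables get counts (%) per level and a chi-square p.
    With a single cluster no p-values are emitted.
    """
    catalog = cohort.catalog
    if variables is None:
        variables = [v for v in catalog.variables]
    clusters = [c for c in sorted(labels.unique())
                if (labels == c).sum() > 0]
    multi = len(clusters) > 1
    rows = []
    rows.append({"variable": "n", "level": "",
                 **{f"cluster_{c}": int((labels == c).sum()) for c in clusters},
                 "p": ""})
    for v in variables:
        vt = catalog.vartype(v)
        col = cohort.data[v]
        if vt in ("continuous", "ordinal"):
            entry = {"variable": v, "level": ""}
            for c in clusters:
                vals = col[labels == c].dropna()
                entry[f"cluster_{c}"] = (f"{vals.mean():.2f} ({vals.std():.2f})"
                                         if len(vals) else "-")
            if multi:
                _, p = kruskal_wallis(col.to_numpy(float),
                                      labels.to_numpy())
                entry["p"] = f"{p:.3g}"
            else:
                entry["p"] = ""
            rows.append(entry)
        else:
            ct = pd.crosstab(col, labels)
            if multi and ct.shape[0] > 1:
                _, chi_p, _, _ = sps.chi2_contingency(ct.to_numpy())
            else:
                chi_p = None
            for li, lev in enumerate(ct.index):
                entry = {"variable": v, "level": str(lev)}
                for c in clusters:
                    cnt = int(ct.loc[lev, c]) if c in ct.columns else 0
                    tot = int((labels == c).sum())
                    entry[f"cluster_{c}"] = f"{cnt} ({100 * cnt / tot:.0f}%)"
                entry["p"] = (f"{chi_p:.3g}" if (chi_p is not None and li == 0)
                              else "")
                rows.append(entry)
    return pd.DataFrame(rows)


# -- thin plotting over the computed surfaces ---------------------------

def plot_parallel_coordinates(profile: QuantileProfile, path=None):
    """Parallel-coordinates plot of cluster median quantiles with CI bands."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = profile.order
    xs = np.arange(len(order))
    fig, ax = plt.subplots(figsize=(max(6, 0.5 * len(order)), 4))
    for c in profile.medians.index:
        med = profile.medians.loc[c, order].to_numpy(float)
        lo = profile.lower.loc[c, order].to_numpy(float)
        hi = profile.upper.loc[c, order].to_numpy(float)
        line, = ax.plot(xs, med, marker="o", label=f"cluster {c}")
        ax.fill_between(xs, lo, hi, alpha=0.15, color=line.get_color())
    ax.set_xticks(xs)
    ax.set_xticklabels(order, rotation=90, fontsize=7)
    ax.set_ylabel("severity quantile (0 = healthiest)")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig


def plot_heatmap(hm: HeatmapMatrix, path=None):
    """Three-color heatmap of the signed pairwise calls, dendrogram-ordered."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    M = hm.ordered()
    fig, ax = plt.subplots(figsize=(max(4, 0.4 * M.shape[1]),
                                    max(3, 0.25 * max(M.shape[0], 1))))
    cmap = ListedColormap(["#7b3294", "#40e0d0", "#ffd700"])  # -1, 0, +1
    ax.imshow(M.to_numpy() if M.size else np.zeros((1, 1)),
              cmap=cmap, vmin=-1, vmax=1, aspect="auto")
    ax.set_xticks(range(M.shape[1]))
    ax.set_xticklabels(M.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(M.shape[0]))
    ax.set_yticklabels(M.index, fontsize=6)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
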