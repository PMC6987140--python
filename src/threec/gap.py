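"""Gap statistic for suggesting the number of clusters.

Compares the log within-cluster dispersion of the data against its
expectation under a structureless reference (uniform draws over the
per-feature range box), clustered by the same PAM/Manhattan procedure.
Consistent with the Manhattan metric, the dispersion uses Manhattan
pairwise distances:

    W_k = sum_r D_r / (2 n_r),   D_r = sum over ordered within-cluster
                                        pairs of d(x_i, x_j)

    gap(k) = E*[log W_k*] - log W_k
    s_k    = sd_b(log W_k*) * sqrt(1 + 1/B)

The curve is advisory: the study design treats the final k as an expert
choice among the candidates the curve suggests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .kmedoids import _as_matrix, kmedoids_manhattan


@dataclass
class GapCurve:
    """Gap statistic over a contiguous k range."""

    k_values: np.ndarray          # evaluated k's, ascending
    log_w: np.ndarray             # log W_k on the data
    log_w_ref: np.ndarray         # mean over B references of log W_k*
    gap: np.ndarray               # log_w_ref - log_w
    s_k: np.ndarray               # reference sd * sqrt(1 + 1/B)
    B: int
    seed: int | None = None

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"k": self.k_values, "log_w": self.log_w,
                             "log_w_ref": self.log_w_ref, "gap": self.gap,
                             "s_k": self.s_k})


def within_dispersion(X: np.ndarray, labels: np.ndarray) -> float:
    """W = sum over clusters of (pairwise Manhattan distance sum) / (2 n_r).

    The pair sum counts both orders, i.e. twice the unordered-pair sum.
    """
    X = np.asarray(X, dtype=float)
    w = 0.0
    for g in np.unique(labels):
        rows = X[labels == g]
        if len(rows) > 1:
            w += 2.0 * pdist(rows, metric="cityblock").sum() / (2.0 * len(rows))
    return w


def gap_statistic(cm_block: pd.DataFrame | np.ndarray,
                  k_range: range | list[int] = range(1, 9),
                  B: int = 50, seed: int = 0) -> GapCurve:
    """Compute the gap curve over ``k_range`` with ``B`` reference draws.

    Reference data sets are drawn uniformly over the observed per-feature
    [min, max] box and clustered identically to the data.
    """
    X = _as_matrix(cm_block)
    ks = np.array(sorted(k_range), dtype=int)
    if B < 10:
        raise ValueError("B must be >= 10 for a usable reference spread")
    lo, hi = X.min(axis=0), X.max(axis=0)
    if np.all(hi == lo):
        raise ValueError("degenerate (constant) data: gap statistic undefined")
    n_distinct = len(np.unique(X, axis=0))
    if ks.max() > n_distinct:
        raise ValueError(f"k range exceeds {n_distinct} distinct rows")

    rng = np.random.default_rng(seed)
    refs = [lo + rng.random(X.shape) * (hi - lo) for _ in range(B)]

    log_w = np.empty(len(ks))
    log_w_ref = np.empty(len(ks))
    s_k = np.empty(len(ks))
    for i, k in enumerate(ks):
        labels = kmedoids_manhattan(X, k).labels.values
        log_w[i] = np.log(within_dispersion(X, labels))
        ref_logs = np.empty(B)
        for b, R in enumerate(refs):
            rl = kmedoids_manhattan(R, k).labels.values
            ref_logs[b] = np.log(within_dispersion(R, rl))
        log_w_ref[i] = ref_logs.mean()
        s_k[i] = ref_logs.std(ddof=0) * np.sqrt(1.0 + 1.0 / B)
    return GapCurve(k_values=ks, log_w=log_w, log_w_ref=log_w_ref,
                    gap=log_w_ref - log_w, s_k=s_k, B=B, seed=seed)


def choose_k_candidates(curve: GapCurve) -> list[int]:
    """Advisory k candidates from the gap curve's drop structure.

    A "drop" at k means gap(k+1) < gap(k).  With two or more drops the
    candidates are the inclusive range from the first drop's k through the
    second drop's k (the study's printed curve dropped after 3 and after 8,
    suggesting 3-8).  With fewer than two drops, the classical one-standard-
    error rule is returned as a singleton: the smallest k with
    gap(k) >= gap(k+1) - s(k+1).
    """
    ks, gap, s = curve.k_values, curve.gap, curve.s_k
    if np.any(np.diff(ks) != 1):
        raise ValueError("curve must cover a contiguous k range")
    drops = [int(ks[i]) for i in range(len(ks) - 1) if gap[i + 1] < gap[i]]
    if len(drops) >= 2:
        return list(range(drops[0], drops[1] + 1))
    for i in range(len(ks) - 1):
        if gap[i] >= gap[i + 1] - s[i + 1]:
            return [int(ks[i])]
    warnings.warn("gap curve increases monotonically; no drop found — "
                  "returning the largest evaluated k")
    return [int(ks[-1])]
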