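"""Rank-based tests and false-discovery-rate machinery.

The biomarker classification stage is exclusively rank-based: a
Kruskal-Wallis screen across clusters, pairwise two-sample Wilcoxon
rank-sum tests, Benjamini-Hochberg step-up FDR control, and the
Benjamini-Bogomolov reduced level q*S/M used when families of pairwise
tests are only examined for biomarkers that survived screening.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "kruskal_wallis",
    "wilcoxon_rank_sum",
    "benjamini_hochberg",
    "bb_adjusted_level",
]

#: above this pooled sample size the Wilcoxon p-value switches from exact
#: enumeration to the tie/continuity-corrected normal approximation
EXACT_WILCOXON_MAX_N = 20


def kruskal_wallis(values, labels) -> tuple[float, float]:
    """Kruskal-Wallis H test across the groups defined by ``labels``.

    Uses midranks and the standard tie correction; p from the upper tail of
    chi-square with (groups - 1) degrees of freedom.  A constant input is
    degenerate: H = 0, p = 1.

    Returns
    -------
    (H, p)
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = [values[labels == g] for g in np.unique(labels)]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 groups with >= 1 observation each")
    if np.ptp(values) == 0:
        return 0.0, 1.0
    try:
        h, p = sps.kruskal(*groups)
    except ValueError:  # scipy rejects all-identical values
        return 0.0, 1.0
    return float(h), float(p)


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon (Mann-Whitney) rank-sum p-value.

    Exact enumeration when m + n <= 20 and the pooled sample is tie-free;
    otherwise the normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= EXACT_WILCOXON_MAX_N and not ties) \
        else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(min(res.pvalue, 1.0))


def benjamini_hochberg(pvalues, level: float = 0.05
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up procedure.

    Rejects every p_(i) with i <= max{i : p_(i) <= i * level / m} and
    returns the monotone step-up adjusted p-values; ties are handled
    jointly (equal p-values share a decision).

    Returns
    -------
    (rejected, p_adjusted) : boolean and float arrays aligned with input
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, bool), np.zeros(0)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    rejected, p_adj, _, _ = multipletests(p, alpha=level, method="fdr_bh")
    return rejected, p_adj


def bb_adjusted_level(q: float, S: int, M: int) -> float:
    """Benjamini-Bogomolov reduced testing level q * S / M.

    After screening M candidate families down to S selected ones, testing
    within each selected family at level q*S/M keeps the average FDR over
    the selected families at q.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    if not 0 <= S <= M:
        raise ValueError("S must satisfy 0 <= S <= M")
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    return q * S / M
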