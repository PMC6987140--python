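"""Biomarker signatures: which pBMs separate which cluster pairs.

Stage 1 screens the pBMs with a Kruskal-Wallis test across clusters and
Benjamini-Hochberg control at budget q.  Stage 2 tests, for each selected
pBM, every unordered cluster pair with the two-sample Wilcoxon rank-sum
test; because the pairwise families are only examined after selection,
they are tested at the Benjamini-Bogomolov reduced level q*S/M (BH within
each selected pBM's family by default; a pooled-BH mode over all pairwise
p-values is available behind a flag).  Signs follow the mean-rank
direction: +1 means the first cluster of the pair sits higher.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .stats import (benjamini_hochberg, bb_adjusted_level, kruskal_wallis,
                    wilcoxon_rank_sum)


@dataclass
class FdrConfig:
    """FDR budget and the screening bookkeeping that sets the pair level."""

    q: float = 0.05
    #: pool all selected pBMs' pairwise p-values into one BH family
    pooled_pairwise: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.q < 1.0:
            raise ValueError("q must lie in (0, 1)")


@dataclass
class SignatureTable:
    """Screening outcomes plus signed pairwise calls.

    ``screen`` is indexed by pBM with columns H, p, p_adj, selected;
    ``pairs`` is tidy with columns pbm, cluster_a, cluster_b (a < b),
    p, sign where sign = +1 if cluster_a's mean rank is larger, -1 if
    smaller, 0 if not significant at the adjusted level (or untestable).
    """

    screen: pd.DataFrame
    pairs: pd.DataFrame
    clusters: list[int]
    q: float
    M: int
    S: int
    adjusted_level: float

    @property
    def selected(self) -> list[str]:
        return self.screen.index[self.screen["selected"]].tolist()

    @property
    def pair_labels(self) -> list[tuple[int, int]]:
        return list(combinations(self.clusters, 2))

    def sign(self, pbm: str, a: int, b: int) -> int:
        """Signed call for (a, b); antisymmetric under pair reversal."""
        lo, hi = min(a, b), max(a, b)
        row = self.pairs[(self.pairs["pbm"] == pbm) &
                         (self.pairs["cluster_a"] == lo) &
                         (self.pairs["cluster_b"] == hi)]
        if row.empty:
            raise KeyError(f"no pair entry for {pbm!r} ({a}, {b})")
        s = int(row["sign"].iloc[0])
        return s if (a, b) == (lo, hi) else -s

    # -- io --------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        rows = []
        for pbm, r in self.screen.iterrows():
            sub = self.pairs[self.pairs["pbm"] == pbm]
            if sub.empty:
                rows.append({"pbm": pbm, "H": r["H"], "p": r["p"],
                             "p_adj": r["p_adj"], "selected": r["selected"],
                             "pair": "", "pair_p": "", "sign": ""})
            else:
                for _, pr in sub.iterrows():
                    rows.append({"pbm": pbm, "H": r["H"], "p": r["p"],
                                 "p_adj": r["p_adj"], "selected": r["selected"],
                                 "pair": f"{pr['cluster_a']}-{pr['cluster_b']}",
                                 "pair_p": pr["p"], "sign": int(pr["sign"])})
        pd.DataFrame(rows).to_csv(path, index=False)


def build_signature_table(pbm_block: pd.DataFrame, cluster_labels,
                          config: FdrConfig | None = None) -> SignatureTable:
    """Screen pBMs across clusters, then sign the pairwise differences.

    Clusters with fewer than two subjects make their pairs untestable
    (sign 0, p absent) rather than erroring out.
    """
    config = config or FdrConfig()
    labels = np.asarray(cluster_labels)
    clusters = sorted(int(c) for c in np.unique(labels))
    if len(clusters) < 2:
        raise ValueError("need >= 2 clusters")
    M = pbm_block.shape[1]
    if M == 0:
        raise ValueError("no pBMs to test")

    # ---- stage 1: KW screen with BH at q --------------------------------
    hs, ps = np.empty(M), np.empty(M)
    for j, var in enumerate(pbm_block.columns):
        hs[j], ps[j] = kruskal_wallis(pbm_block[var].to_numpy(), labels)
    rejected, p_adj = benjamini_hochberg(ps, config.q)
    screen = pd.DataFrame({"H": hs, "p": ps, "p_adj": p_adj,
                           "selected": rejected},
                          index=pd.Index(pbm_block.columns, name="pbm"))
    selected = screen.index[screen["selected"]].tolist()
    S = len(selected)
    level = bb_adjusted_level(config.q, S, M)

    # ---- stage 2: pairwise Wilcoxon at the reduced level ----------------
    groups = {c: np.flatnonzero(labels == c) for c in clusters}
    records = []
    for pbm in selected:
        x = pbm_block[pbm].to_numpy(dtype=float)
        mean_ranks = pd.Series(x).rank().groupby(labels).mean()
        for a, b in combinations(clusters, 2):
            if len(groups[a]) < 2 or len(groups[b]) < 2:
                records.append({"pbm": pbm, "cluster_a": a, "cluster_b": b,
                                "p": np.nan, "sign": 0, "testable": False})
                continue
            p = wilcoxon_rank_sum(x[groups[a]], x[groups[b]])
            direction = 1 if mean_ranks[a] > mean_ranks[b] else -1
            records.append({"pbm": pbm, "cluster_a": a, "cluster_b": b,
                            "p": p, "sign": direction, "testable": True})
    pairs = pd.DataFrame(records, columns=["pbm", "cluster_a", "cluster_b",
                                           "p", "sign", "testable"])
    if len(pairs) and S > 0 and level > 0:
        testable = pairs["testable"].to_numpy()
        rej = np.zeros(len(pairs), dtype=bool)
        if config.pooled_pairwise:
            if testable.any():
                rej[testable], _ = benjamini_hochberg(
                    pairs.loc[testable, "p"].to_numpy(), level)
        else:
            for pbm in selected:
                fam = (pairs["pbm"] == pbm).to_numpy() & testable
                if fam.any():
                    rej[fam], _ = benjamini_hochberg(
                        pairs.loc[fam, "p"].to_numpy(), level)
        pairs.loc[~rej, "sign"] = 0
    elif len(pairs):
        pairs["sign"] = 0
    pairs = pairs.drop(columns="testable")
    return SignatureTable(screen=screen, pairs=pairs, clusters=clusters,
                          q=config.q, M=M, S=S, adjusted_level=level)


def signature_for_cluster(table: SignatureTable, cluster: int
                          ) -> dict[str, dict[tuple[int, int], int]]:
    """The cluster's subtype signature: pBMs with a signed pair touching it.

    Returns a mapping pBM -> {(cluster, other): sign}, with the pair
    oriented so the queried cluster comes first (sign antisymmetry).
    """
    if cluster not in table.clusters:
        raise KeyError(f"unknown cluster {cluster}")
    out: dict[str, dict[tuple[int, int], int]] = {}
    touching = table.pairs[
        ((table.pairs["cluster_a"] == cluster) |
         (table.pairs["cluster_b"] == cluster)) & (table.pairs["sign"] != 0)]
    for _, row in touching.iterrows():
        a, b, s = int(row["cluster_a"]), int(row["cluster_b"]), int(row["sign"])
        other = b if a == cluster else a
        oriented = s if a == cluster else -s
        out.setdefault(row["pbm"], {})[(cluster, other)] = oriented
    return out
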