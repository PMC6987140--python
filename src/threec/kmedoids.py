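"""Partitioning Around Medoids (PAM) with the Manhattan distance.

Subjects are clustered around observed exemplar rows (medoids), which keeps
cluster centers interpretable as actual patients.  The implementation is
the classical PAM pair: a greedy cost-minimizing BUILD initialization
followed by SWAP passes that apply the single best medoid <-> non-medoid
exchange while the total cost strictly decreases.  All tie-breaks are by
lowest index, so the result is deterministic given the data order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist


@dataclass
class ClusterModel:
    """A fitted k-medoids clustering.

    Labels are 1-based cluster indices ordered by medoid position in
    ``medoid_ids``.  ``cost`` is the sum over subjects of the Manhattan
    distance to their own medoid.
    """

    k: int
    medoid_ids: list
    medoid_rows: pd.DataFrame        # k x p, indexed by medoid id
    labels: pd.Series                # subject id -> cluster label in 1..k
    cost: float
    seed: int | None = None
    columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.columns:
            self.columns = list(self.medoid_rows.columns)

    @property
    def cluster_ids(self) -> list[int]:
        return list(range(1, self.k + 1))

    # -- persistence -----------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "k": self.k,
            "medoid_ids": [str(m) for m in self.medoid_ids],
            "columns": self.columns,
            "medoid_rows": self.medoid_rows[self.columns].values.tolist(),
            "labels": {str(s): int(v) for s, v in self.labels.items()},
            "cost": self.cost,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ClusterModel":
        d = json.loads(Path(path).read_text())
        rows = pd.DataFrame(d["medoid_rows"], columns=d["columns"],
                            index=d["medoid_ids"])
        labels = pd.Series(d["labels"], name="cluster").astype(int)
        return cls(k=d["k"], medoid_ids=d["medoid_ids"], medoid_rows=rows,
                   labels=labels, cost=d["cost"], seed=d["seed"],
                   columns=d["columns"])


def _as_matrix(cm_block: pd.DataFrame | np.ndarray) -> np.ndarray:
    X = np.asarray(cm_block, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D subject x variable block")
    if not np.isfinite(X).all():
        raise ValueError("clustering input contains missing or non-finite "
                         "values; run complete-case filtering first")
    return X


def _pam_build(D: np.ndarray, k: int) -> list[int]:
    """Greedy BUILD: repeatedly add the medoid giving the largest cost drop."""
    n = D.shape[0]
    first = int(np.argmin(D.sum(axis=0)))
    medoids = [first]
    nearest = D[:, first].copy()
    while len(medoids) < k:
        # gain[j] = total reduction in nearest-distance if j became a medoid
        gain = np.maximum(nearest[:, None] - D, 0.0).sum(axis=0)
        gain[medoids] = -np.inf
        j = int(np.argmax(gain))
        medoids.append(j)
        nearest = np.minimum(nearest, D[:, j])
    return medoids


def _pam_swap(D: np.ndarray, medoids: list[int]) -> list[int]:
    """SWAP passes: best single exchange while total cost strictly drops."""
    n = D.shape[0]
    medoids = list(medoids)
    while True:
        Dm = D[:, medoids]                       # n x k
        order = np.argsort(Dm, axis=1, kind="stable")
        near_idx = order[:, 0]                   # index into medoids
        d1 = Dm[np.arange(n), near_idx]
        d2 = Dm[np.arange(n), order[:, 1]] if len(medoids) > 1 \
            else np.full(n, np.inf)
        # shared term: points keeping their medoid can still defect to h
        base = np.minimum(0.0, D - d1[:, None])  # n x n, over candidate h
        base_sum = base.sum(axis=0)
        best_delta, best_swap = 0.0, None
        for mi, m in enumerate(medoids):
            owned = near_idx == mi
            # owned points must leave m: go to h or to their second-best
            reassign = np.minimum(D[owned], d2[owned, None]) - d1[owned, None]
            delta = base_sum - base[owned].sum(axis=0) + reassign.sum(axis=0)
            delta[medoids] = np.inf
            h = int(np.argmin(delta))
            if delta[h] < best_delta - 1e-12:
                best_delta, best_swap = float(delta[h]), (mi, h)
        if best_swap is None:
            return medoids
        medoids[best_swap[0]] = best_swap[1]


def kmedoids_manhattan(cm_block: pd.DataFrame | np.ndarray, k: int,
                       seed: int | None = None, n_restarts: int = 2
                       ) -> ClusterModel:
    """Cluster subjects into ``k`` groups by PAM under Manhattan distance.

    Runs BUILD + SWAP, plus ``n_restarts`` seeded random-initialization
    SWAP runs to escape the rare local optima BUILD can land in; the
    lowest-cost solution wins (BUILD's kept on ties).  Deterministic
    given the data order and seed.

    Parameters
    ----------
    cm_block : DataFrame or array, subjects x screened CM variables
    k : number of clusters; must not exceed the number of distinct rows
    seed : drives the restart initializations; recorded in the model

    Returns
    -------
    ClusterModel
    """
    X = _as_matrix(cm_block)
    n = X.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    n_distinct = len(np.unique(X, axis=0))
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct rows")
    D = cdist(X, X, metric="cityblock")

    def total_cost(meds):
        return float(D[:, meds].min(axis=1).sum())

    medoids = _pam_swap(D, _pam_build(D, k))
    best_cost = total_cost(medoids)
    rng = np.random.default_rng(0 if seed is None else seed)
    for _ in range(n_restarts):
        cand = _pam_swap(D, list(rng.choice(n, size=k, replace=False)))
        if total_cost(cand) < best_cost - 1e-12:
            medoids, best_cost = cand, total_cost(cand)
    assign = np.argmin(D[:, medoids], axis=1)    # ties -> lowest medoid index
    cost = float(D[np.arange(n), [medoids[a] for a in assign]].sum())

    if isinstance(cm_block, pd.DataFrame):
        index = cm_block.index
        columns = list(cm_block.columns)
    else:
        index = pd.RangeIndex(n)
        columns = [f"x{i}" for i in range(X.shape[1])]
    medoid_ids = [index[m] for m in medoids]
    medoid_rows = pd.DataFrame(X[medoids], index=medoid_ids, columns=columns)
    labels = pd.Series(assign + 1, index=index, name="cluster")
    return ClusterModel(k=k, medoid_ids=medoid_ids, medoid_rows=medoid_rows,
                        labels=labels, cost=cost, seed=seed, columns=columns)


def assign_new_subjects(model: ClusterModel,
                        cm_rows: pd.DataFrame | np.ndarray) -> pd.Series:
    """Label new subjects by their nearest medoid (Manhattan, ties -> lowest).

    ``cm_rows`` must carry the model's screened CM columns (any order for a
    DataFrame; positional for an array).
    """
    if isinstance(cm_rows, pd.DataFrame):
        missing = [c for c in model.columns if c not in cm_rows.columns]
        if missing:
            raise ValueError(f"rows lack the model's columns: {missing}")
        X = _as_matrix(cm_rows[model.columns])
        index = cm_rows.index
    else:
        X = _as_matrix(cm_rows)
        if X.shape[1] != len(model.columns):
            raise ValueError(
                f"expected {len(model.columns)} columns, got {X.shape[1]}")
        index = pd.RangeIndex(X.shape[0])
    D = cdist(X, model.medoid_rows[model.columns].values, metric="cityblock")
    return pd.Series(np.argmin(D, axis=1) + 1, index=index, name="cluster")
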