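"""Supervised relevance screening of clinical measurements.

Before clustering, CMs are screened for relevance to the assigned
diagnosis so that irrelevant variables do not drown the Manhattan
distances.  The screen is the two-stage variable-importance procedure of
random-forest selection ("thresholding" then "interpretation"):

Stage 1 (thresholding)
    Fit ``n_forests_threshold`` independent forests of DX on all CMs and
    average each CM's out-of-bag permutation importance.  The elimination
    threshold is the minimum of a regression-tree fit of the importance
    standard deviations against importance rank — the plateau of sd among
    the irrelevant variables; CMs whose mean importance falls below it
    are dropped.

Stage 2 (interpretation)
    Order survivors by mean importance and fit nested forests on the
    top-1, top-2, ... prefixes (``n_forests_interpretation`` forests
    each).  The selected set is the smallest prefix whose mean out-of-bag
    error is within one standard deviation (of the best prefix's errors)
    of the minimum.

Forests are bagged scikit-learn decision trees with sqrt feature
sampling; the bootstrap is drawn here so out-of-bag membership is exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor


@dataclass
class ScreeningParams:
    """Forest counts follow the selection method's published defaults."""

    n_forests_threshold: int = 50
    n_forests_interpretation: int = 25
    n_trees: int = 100
    seed: int = 0


@dataclass
class ScreeningResult:
    """Outcome of the two-stage screen.

    ``table`` has one row per CM: mean_importance, sd_importance,
    selected, stage (``threshold`` / ``interpretation`` = eliminated
    there, ``kept`` = selected).
    """

    table: pd.DataFrame
    selected: list[str]
    threshold: float
    prefix_errors: pd.DataFrame     # per prefix size: mean/sd OOB error
    params: ScreeningParams = field(default_factory=ScreeningParams)

    def __post_init__(self) -> None:
        if not self.selected:
            raise ValueError("screening produced an empty selection")


class _Forest:
    """Bagged trees with explicit bootstrap so OOB sets are known exactly."""

    def __init__(self, n_trees: int, rng: np.random.Generator):
        self.n_trees = n_trees
        self.rng = rng
        self.trees: list[DecisionTreeClassifier] = []
        self.oob_masks: list[np.ndarray] = []

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_Forest":
        n = len(y)
        for _ in range(self.n_trees):
            idx = self.rng.integers(0, n, size=n)
            oob = np.ones(n, dtype=bool)
            oob[idx] = False
            tree = DecisionTreeClassifier(
                max_features="sqrt",
                random_state=int(self.rng.integers(2 ** 31)))
            tree.fit(X[idx], y[idx])
            self.trees.append(tree)
            self.oob_masks.append(oob)
        self._X, self._y = X, y
        return self

    def oob_error(self) -> float:
        """Majority-vote OOB misclassification rate."""
        n = len(self._y)
        n_classes = int(self._y.max()) + 1
        votes = np.zeros((n, n_classes))
        for tree, oob in zip(self.trees, self.oob_masks):
            if oob.sum() == 0:
                continue
            pred = tree.predict(self._X[oob]).astype(int)
            votes[np.flatnonzero(oob), pred] += 1
        covered = votes.sum(axis=1) > 0
        if not covered.any():        # pragma: no cover - tiny-n guard
            return np.nan
        pred = votes[covered].argmax(axis=1)
        return float((pred != self._y[covered]).mean())

    def oob_permutation_importance(self) -> np.ndarray:
        """Mean over trees of (permuted OOB error - OOB error) per feature."""
        d = self._X.shape[1]
        imp = np.zeros(d)
        used = 0
        for tree, oob in zip(self.trees, self.oob_masks):
            m = int(oob.sum())
            if m == 0:
                continue
            Xo = self._X[oob]
            yo = self._y[oob]
            base = float((tree.predict(Xo).astype(int) != yo).mean())
            stacked = np.repeat(Xo[None, :, :], d, axis=0)
            for j in range(d):
                stacked[j, :, j] = self.rng.permutation(Xo[:, j])
            preds = tree.predict(stacked.reshape(d * m, d)).astype(int)
            imp += (preds.reshape(d, m) != yo).mean(axis=1) - base
            used += 1
        return imp / max(used, 1)


def _sd_threshold(mean_imp: np.ndarray, sd_imp: np.ndarray) -> float:
    """Threshold = min of a regression-tree fit of sd against importance rank."""
    order = np.argsort(-mean_imp, kind="stable")
    ranks = np.arange(1, len(order) + 1, dtype=float).reshape(-1, 1)
    sd_sorted = sd_imp[order]
    leaf = max(2, len(order) // 10)
    tree = DecisionTreeRegressor(min_samples_leaf=leaf, random_state=0)
    tree.fit(ranks, sd_sorted)
    return float(tree.predict(ranks).min())


def rf_importance_screen(cm_block: pd.DataFrame, dx_labels,
                         params: ScreeningParams | None = None
                         ) -> ScreeningResult:
    """Two-stage forest-importance screen of CMs against the DX label."""
    params = params or ScreeningParams()
    X = np.asarray(cm_block, dtype=float)
    names = list(cm_block.columns) if isinstance(cm_block, pd.DataFrame) \
        else [f"cm{i}" for i in range(X.shape[1])]
    classes, y = np.unique(np.asarray(dx_labels), return_inverse=True)
    if len(classes) < 2:
        raise ValueError("need >= 2 DX levels")
    if X.shape[1] < 2:
        raise ValueError("need >= 2 CMs")
    if X.shape[0] < 20:
        raise ValueError("need >= 20 subjects")
    if not np.isfinite(X).all():
        raise ValueError("CM block must be complete")

    rng = np.random.default_rng(params.seed)

    # ---- stage 1: thresholding -----------------------------------------
    imps = np.empty((params.n_forests_threshold, X.shape[1]))
    for f in range(params.n_forests_threshold):
        forest = _Forest(params.n_trees, rng).fit(X, y)
        imps[f] = forest.oob_permutation_importance()
    mean_imp = imps.mean(axis=0)
    sd_imp = imps.std(axis=0, ddof=1)
    thr = _sd_threshold(mean_imp, sd_imp)
    survivors = [i for i in np.argsort(-mean_imp, kind="stable")
                 if mean_imp[i] >= thr]
    if not survivors:
        warnings.warn("no CM importance cleared the threshold; "
                      "falling back to the single top variable")
        survivors = [int(np.argmax(mean_imp))]

    # ---- stage 2: interpretation ---------------------------------------
    errs_mean = np.empty(len(survivors))
    errs_sd = np.empty(len(survivors))
    for p in range(1, len(survivors) + 1):
        cols = survivors[:p]
        errs = np.empty(params.n_forests_interpretation)
        for f in range(params.n_forests_interpretation):
            errs[f] = _Forest(params.n_trees, rng).fit(X[:, cols], y).oob_error()
        errs_mean[p - 1] = errs.mean()
        errs_sd[p - 1] = errs.std(ddof=1) if len(errs) > 1 else 0.0
    best = int(np.argmin(errs_mean))
    cutoff = errs_mean[best] + errs_sd[best]
    n_sel = 1 + int(np.argmax(errs_mean <= cutoff))
    selected_idx = survivors[:n_sel]

    stage = np.full(X.shape[1], "threshold", dtype=object)
    stage[survivors] = "interpretation"
    stage[selected_idx] = "kept"
    table = pd.DataFrame({
        "mean_importance": mean_imp,
        "sd_importance": sd_imp,
        "selected": stage == "kept",
        "stage": stage,
    }, index=pd.Index(names, name="variable"))
    prefix_errors = pd.DataFrame({
        "prefix_size": np.arange(1, len(survivors) + 1),
        "mean_oob_error": errs_mean,
        "sd_oob_error": errs_sd,
    })
    return ScreeningResult(table=table, selected=[names[i] for i in selected_idx],
                           threshold=thr, prefix_errors=prefix_errors,
                           params=params)
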