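"""Data reduction: complete cases, redundancy removal, composites, transforms.

The study avoided imputation on purpose — missingness there was informative
of diagnosis — and instead reduced to complete cases: variables with too
many gaps are dropped first, then every subject still carrying a gap.
Redundant variables (near-perfect correlation, or near-constant discrete
variables by Gini impurity) are removed, cognitive-domain composites are
added as item sums, and each continuous variable may be re-expressed by
the monotone transform that best symmetrizes it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import Cohort, VariableCatalog


class EmptyResultError(ValueError):
    """Complete-case filtering removed everything."""

    def __init__(self, message: str, report: dict):
        super().__init__(message)
        self.report = report


@dataclass
class PreprocessConfig:
    max_var_missing_frac: float = 0.3
    corr_threshold: float = 0.99
    gini_threshold: float = 0.05
    #: candidate monotone transforms tried by monotone_transform, in order
    transform_family: tuple[str, ...] = ("identity", "log", "sqrt",
                                         "rank_normal")
    #: domain tag -> list of item variables summed into a composite CM
    domain_map: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for v in (self.max_var_missing_frac, self.corr_threshold,
                  self.gini_threshold):
            if not 0.0 <= v <= 1.0:
                raise ValueError("thresholds must lie in [0, 1]")
        unknown = set(self.transform_family) - set(_TRANSFORMS)
        if unknown:
            raise ValueError(f"unknown transforms: {sorted(unknown)}")


def complete_case_filter(cohort: Cohort, config: PreprocessConfig
                         ) -> Cohort:
    """Two-step reduction to a gap-free cohort.

    (1) drop every variable whose missing fraction exceeds
    ``max_var_missing_frac``; (2) drop every subject with any remaining
    missing cell.  The filter report (what was dropped and why) is stored
    under ``meta['complete_case_report']``.
    """
    miss_frac = cohort.data.isna().mean(axis=0)
    drop_vars = miss_frac.index[miss_frac > config.max_var_missing_frac].tolist()
    kept = cohort.data.drop(columns=drop_vars)
    drop_subjects = kept.index[kept.isna().any(axis=1)].tolist()
    kept = kept.drop(index=drop_subjects)
    report = {
        "variables_dropped": drop_vars,
        "variable_missing_frac": {v: float(miss_frac[v]) for v in drop_vars},
        "subjects_dropped": [str(s) for s in drop_subjects],
        "n_variables": int(kept.shape[1]),
        "n_subjects": int(kept.shape[0]),
    }
    if kept.shape[1] == 0 or kept.shape[0] == 0:
        raise EmptyResultError("complete-case filtering removed every "
                               "variable or subject", report)
    meta = dict(cohort.meta)
    meta["complete_case_report"] = report
    return Cohort(kept, cohort.catalog.subset(kept.columns), meta)


def gini_impurity(values: pd.Series | np.ndarray) -> float:
    """1 - sum of squared class proportions over observed values."""
    counts = pd.Series(values).dropna().value_counts().to_numpy(float)
    if counts.sum() == 0:
        return 0.0
    p = counts / counts.sum()
    return float(1.0 - (p ** 2).sum())


def remove_redundant(cohort: Cohort, config: PreprocessConfig) -> Cohort:
    """Drop near-duplicate continuous variables and near-constant discrete ones.

    For each pair of continuous variables with |Pearson r| above
    ``corr_threshold``, the later one in catalog order goes; discrete
    (ordinal/categorical) variables with Gini impurity below
    ``gini_threshold`` go; zero-variance continuous variables count as
    constant.  Idempotent.  Report stored under ``meta['redundancy_report']``.
    """
    if not cohort.is_complete():
        raise ValueError("remove_redundant expects a complete cohort")
    catalog = cohort.catalog
    drops: list[dict] = []
    dropped: set[str] = set()

    cont = [v for v in catalog.variables
            if catalog.vartype(v) == "continuous"
            and catalog.table.set_index("variable").loc[v, "category"] != "DX"]
    for v in cont:
        if cohort.data[v].nunique() <= 1:
            dropped.add(v)
            drops.append({"variable": v, "reason": "constant"})
    alive = [v for v in cont if v not in dropped]
    if len(alive) > 1:
        corr = cohort.data[alive].corr(method="pearson").abs().to_numpy()
        for j in range(1, len(alive)):
            if alive[j] in dropped:
                continue
            for i in range(j):
                if alive[i] in dropped:
                    continue
                if corr[i, j] > config.corr_threshold:
                    dropped.add(alive[j])
                    drops.append({"variable": alive[j],
                                  "reason": f"corr>{config.corr_threshold} "
                                            f"with {alive[i]}"})
                    break

    discrete = [v for v in catalog.variables
                if catalog.vartype(v) in ("ordinal", "categorical")
                and catalog.table.set_index("variable").loc[v, "category"] != "DX"]
    for v in discrete:
        g = gini_impurity(cohort.data[v])
        if g < config.gini_threshold:
            dropped.add(v)
            drops.append({"variable": v, "reason": f"gini={g:.4f}"})

    kept_cols = [c for c in cohort.data.columns if c not in dropped]
    meta = dict(cohort.meta)
    meta["redundancy_report"] = drops
    return Cohort(cohort.data[kept_cols].copy(), catalog.subset(kept_cols), meta)


def domain_sum_scores(cohort: Cohort, config: PreprocessConfig) -> Cohort:
    """Append one composite CM per domain: the row-wise sum of its items.

    All items of a domain must share a severity direction (the composite
    inherits it); originals are retained.
    """
    if not config.domain_map:
        return cohort
    data = cohort.data.copy()
    catalog = cohort.catalog
    for domain, items in config.domain_map.items():
        missing = [v for v in items if v not in data.columns]
        if missing:
            raise ValueError(f"domain {domain!r}: unknown items {missing}")
        dirs = {catalog.direction(v) for v in items}
        if len(dirs) != 1 or dirs == {"none"}:
            raise ValueError(f"domain {domain!r}: items mix severity "
                             f"directions {sorted(dirs)}")
        name = f"{domain}_sum"
        data[name] = data[items].sum(axis=1)
        catalog = catalog.add_variable(name, "CM", "continuous",
                                       dirs.pop(), domain)
    return Cohort(data, catalog, dict(cohort.meta))


# -- monotone transforms ------------------------------------------------

def _rank_normal(x: np.ndarray) -> np.ndarray:
    ranks = sps.rankdata(x)                       # midranks
    return sps.norm.ppf((ranks - 0.5) / len(x))

_TRANSFORMS = {
    "identity": lambda x: x,
    "log": lambda x: np.log(x - x.min() + 1.0),
    "sqrt": lambda x: np.sqrt(x - x.min()),
    "rank_normal": _rank_normal,
}


def monotone_transform(values, family: tuple[str, ...] = ("identity", "log",
                       "sqrt", "rank_normal")) -> tuple[np.ndarray, str]:
    """Re-express a variable by the candidate transform of least |skewness|.

    All candidates are strictly monotone increasing, so ranks are
    preserved; on a constant vector the identity is returned with the
    label ``"degenerate"``.

    Returns
    -------
    (transformed, label)
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 values")
    if not np.isfinite(x).all():
        raise ValueError("values must be complete")
    if np.ptp(x) == 0:
        return x.copy(), "degenerate"
    best_name, best_out, best_skew = None, None, np.inf
    for name in family:
        out = _TRANSFORMS[name](x)
        skew = abs(float(sps.skew(out)))
        if np.isfinite(skew) and skew < best_skew - 1e-12:
            best_name, best_out, best_skew = name, out, skew
    return best_out, best_name


def preprocess(cohort: Cohort, config: PreprocessConfig,
               transform: bool = True) -> Cohort:
    """Full reduction: complete cases, redundancy, composites, transforms.

    Transforms are applied in place to continuous non-DX variables; chosen
    labels are recorded under ``meta['transforms']``.
    """
    out = complete_case_filter(cohort, config)
    out = remove_redundant(out, config)
    out = domain_sum_scores(out, config)
    if transform:
        chosen: dict[str, str] = {}
        data = out.data.copy()
        for v in out.catalog.variables:
            if out.catalog.vartype(v) == "continuous" and \
                    v != out.catalog.dx_variable:
                data[v], chosen[v] = monotone_transform(
                    data[v].to_numpy(), config.transform_family)
        meta = dict(out.meta)
        meta["transforms"] = chosen
        out = Cohort(data, out.catalog, meta)
    return out


def write_report(cohort: Cohort, path: str | Path) -> None:
    """Serialize the accumulated filter/transform reports as JSON."""
    Path(path).write_text(json.dumps(cohort.meta, indent=1, default=str))
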