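"""Model/Results interface over the full Categorize-Cluster-Classify run.

``ThreeCModel`` holds a cohort and the analysis configuration; ``fit``
executes the strategy — categorize the variables, screen the clinical
measurements against the assigned diagnosis, cluster the subjects by
PAM/Manhattan on the screened CMs, then test and sign the biomarkers —
and returns a ``ThreeCResults`` carrying every stage's output plus
``summary()``.  The number of clusters k is a required analyst choice;
the gap curve (``compute_gap=True``) is advisory only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort, VariableCatalog, categorize
from .gap import GapCurve, choose_k_candidates, gap_statistic
from .kmedoids import ClusterModel, kmedoids_manhattan
from .preprocess import PreprocessConfig, preprocess
from .report import (HeatmapMatrix, QuantileProfile, build_heatmap_matrix,
                     characterize_clusters, cluster_quantile_profile)
from .screening import ScreeningParams, ScreeningResult, rf_importance_screen
from .signatures import (FdrConfig, SignatureTable, build_signature_table,
                         signature_for_cluster)


class ThreeCModel:
    """The 3C subtyping analysis bound to one cohort.

    Parameters
    ----------
    cohort : Cohort
        Subject x variable table with its catalog; may contain missing
        cells (they are removed by complete-case preprocessing in fit).
    k : int
        Number of clusters.  Deliberately required: the study design
        treats k as an expert decision informed by the gap curve.
    preprocess_config : PreprocessConfig, optional
    screening_params : ScreeningParams, optional
    fdr_config : FdrConfig, optional
    exclude_cms : sequence of str
        CMs (e.g. demographics) withheld from screening/clustering but
        kept for characterization tables.
    scale_cms : bool
        Standardize the screened CMs (unit sd) before Manhattan
        clustering; off by default.
    transform : bool
        Apply symmetry-improving monotone transforms during
        preprocessing; off by default (rank-based stages are unaffected).
    """

    def __init__(self, cohort: Cohort, k: int, *,
                 preprocess_config: PreprocessConfig | None = None,
                 screening_params: ScreeningParams | None = None,
                 fdr_config: FdrConfig | None = None,
                 exclude_cms: tuple[str, ...] = (),
                 scale_cms: bool = False,
                 transform: bool = False):
        if k < 2:
            raise ValueError("k must be >= 2")
        self.cohort = cohort
        self.k = int(k)
        self.preprocess_config = preprocess_config or PreprocessConfig()
        self.screening_params = screening_params or ScreeningParams()
        self.fdr_config = fdr_config or FdrConfig()
        self.exclude_cms = tuple(exclude_cms)
        self.scale_cms = scale_cms
        self.transform = transform

    @classmethod
    def from_frames(cls, data: pd.DataFrame, catalog: pd.DataFrame,
                    k: int, **kwargs) -> "ThreeCModel":
        """Build from a raw data frame plus a catalog frame."""
        return cls(Cohort(data, VariableCatalog(catalog.copy())), k, **kwargs)

    @classmethod
    def from_csv(cls, data_path, catalog_path, k: int, **kwargs
                 ) -> "ThreeCModel":
        return cls(Cohort.from_csv(data_path, catalog_path), k, **kwargs)

    def fit(self, seed: int = 0, *, compute_gap: bool = False,
            k_range=range(2, 9), gap_B: int = 50) -> "ThreeCResults":
        """Run the full strategy; all randomness derives from ``seed``."""
        children = np.random.SeedSequence(seed).generate_state(3) % (2 ** 31)
        screen_seed, cluster_seed, gap_seed = (int(c) for c in children)

        clean = preprocess(self.cohort, self.preprocess_config,
                           transform=self.transform)
        dx, cm_block, pbm_block = categorize(clean)
        usable_cm = cm_block.drop(columns=[c for c in self.exclude_cms
                                           if c in cm_block.columns])
        params = ScreeningParams(
            n_forests_threshold=self.screening_params.n_forests_threshold,
            n_forests_interpretation=self.screening_params.n_forests_interpretation,
            n_trees=self.screening_params.n_trees,
            seed=screen_seed)
        screening = rf_importance_screen(usable_cm, dx, params)
        features = cm_block[screening.selected]
        if self.scale_cms:
            sd = features.std(ddof=0).replace(0.0, 1.0)
            features = features / sd

        gap_curve = None
        k_candidates: list[int] | None = None
        if compute_gap:
            ks = [k for k in k_range if k <= len(features)]
            gap_curve = gap_statistic(features, ks, B=gap_B, seed=gap_seed)
            k_candidates = choose_k_candidates(gap_curve)

        cluster_model = kmedoids_manhattan(features, self.k, seed=cluster_seed)
        table = build_signature_table(pbm_block, cluster_model.labels.values,
                                      self.fdr_config)
        return ThreeCResults(model=self, clean=clean, dx=dx,
                             cm_block=cm_block, pbm_block=pbm_block,
                             screening=screening, features=features,
                             cluster_model=cluster_model,
                             signature_table=table, gap_curve=gap_curve,
                             k_candidates=k_candidates, seed=seed)


@dataclass
class ThreeCResults:
    """Everything a fitted 3C run produced."""

    model: ThreeCModel
    clean: Cohort                      # preprocessed complete-case cohort
    dx: pd.Series
    cm_block: pd.DataFrame
    pbm_block: pd.DataFrame
    screening: ScreeningResult
    features: pd.DataFrame             # screened (optionally scaled) CMs
    cluster_model: ClusterModel
    signature_table: SignatureTable
    gap_curve: GapCurve | None = None
    k_candidates: list[int] | None = None
    seed: int = 0
    _profiles: dict = field(default_factory=dict, repr=False)

    @property
    def labels(self) -> pd.Series:
        return self.cluster_model.labels

    def cluster_sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()

    # -- report surfaces -------------------------------------------------
    def quantile_profile(self, which: str = "cm", level: float = 0.95
                         ) -> QuantileProfile:
        """Severity-quantile profile of CMs ('cm'), screened CMs
        ('screened'), or significant pBMs ('pbm')."""
        key = (which, level)
        if key not in self._profiles:
            if which == "cm":
                variables = list(self.cm_block.columns)
            elif which == "screened":
                variables = self.screening.selected
            elif which == "pbm":
                sig = self.signature_table.pairs
                variables = sorted(sig.loc[sig["sign"] != 0, "pbm"].unique())
            else:
                raise ValueError(f"unknown profile {which!r}")
            self._profiles[key] = cluster_quantile_profile(
                self.clean, self.labels, variables, level)
        return self._profiles[key]

    def heatmap(self) -> HeatmapMatrix:
        return build_heatmap_matrix(self.signature_table)

    def characterize(self, variables: list[str] | None = None) -> pd.DataFrame:
        return characterize_clusters(self.clean, self.labels, variables)

    def signature_for_cluster(self, cluster: int):
        return signature_for_cluster(self.signature_table, cluster)

    # -- summary ----------------------------------------------------------
    def summary(self) -> str:
        t = self.signature_table
        lines = [
            "3C subtyping results",
            "=" * 60,
            f"subjects (complete cases)    {self.clean.n_subjects}",
            f"clinical measurements (CM)   {self.cm_block.shape[1]}",
            f"potential biomarkers (pBM)   {self.pbm_block.shape[1]}",
            f"screened CMs selected        {len(self.screening.selected)}: "
            f"{', '.join(self.screening.selected)}",
            f"clusters (k)                 {self.cluster_model.k}",
            f"total Manhattan cost         {self.cluster_model.cost:.2f}",
        ]
        if self.k_candidates is not None:
            lines.append(f"gap-curve k candidates       {self.k_candidates}")
        lines += [
            f"cluster sizes                "
            + ", ".join(f"{c}: {n}" for c, n in self.cluster_sizes().items()),
            "-" * 60,
            f"pBM screening (KW + BH, q={t.q}):  selected {t.S} of {t.M}",
            f"pairwise Wilcoxon level      q*S/M = {t.adjusted_level:.6g}",
            f"signed pairwise calls        "
            f"{int((t.pairs['sign'] != 0).sum())} of {len(t.pairs)}",
        ]
        for c in t.clusters:
            sig = self.signature_for_cluster(c)
            lines.append(f"  cluster {c} signature: {len(sig)} pBM(s)")
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------
    def save(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.clean.to_csv(outdir / "clean.csv", outdir / "clean_catalog.csv")
        self.screening.table.to_csv(outdir / "screening.csv")
        self.cluster_model.to_json(outdir / "model.json")
        self.signature_table.to_csv(outdir / "signatures.csv")
        self.quantile_profile("cm").as_frame().to_csv(
            outdir / "profiles.csv", index=False)
        self.heatmap().ordered().to_csv(outdir / "heatmap.csv")
        self.characterize().to_csv(outdir / "summary.csv", index=False)
        if self.gap_curve is not None:
            self.gap_curve.as_frame().to_csv(outdir / "gap.csv", index=False)
        (outdir / "summary.txt").write_text(self.summary() + "\n")
        return outdir
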