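"""Synthetic ADNI-like cohort generator with known ground truth.

The real study data (a restricted Alzheimer's cohort baseline extract) is
not redistributable, so this module emulates its regime with every planted
feature recoverable:

* ``k_true`` subject clusters along a latent severity axis;
* a minority of clinical measurements (CMs) carrying that cluster
  structure, buried among many structureless noise CMs;
* an assigned diagnosis (DX) derived *crudely* from latent severity — a
  five-level quantile cut plus label-shift noise — so DX overlaps the true
  clusters without matching them;
* potential biomarkers (pBMs): some with a location shift in one
  designated cluster, the rest exchangeable across clusters;
* missingness whose probability grows with DX severity, mimicking the
  observation that sicker subjects have more measurements recorded (and
  hence healthier ones more gaps).

Severity directions are randomized (half "higher = worse", half
"higher = better") to force explicit direction handling downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import DX_LEVELS, Cohort, VariableCatalog, dx_severity_level


class ConfigError(ValueError):
    """Raised for impossible generator configurations."""


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic cohort.

    ``effect_size`` is the standardized mean separation between adjacent
    cluster centers on informative CMs (unit noise).  ``pbm_effect_size``
    is the location shift of a signal pBM in its designated cluster; it
    defaults to ``effect_size``.  ``missing_rate_base`` is the MCAR floor
    and ``missing_dx_gradient`` adds that much missingness probability per
    DX severity level (0-4).
    """

    n_subjects: int = 650
    k_true: int = 6
    n_cm_info: int = 5
    n_cm_noise: int = 50
    n_pbm_signal: int = 10
    n_pbm_null: int = 60
    effect_size: float = 4.0
    pbm_effect_size: float | None = None
    dx_noise: float = 0.1
    missing_rate_base: float = 0.0
    missing_dx_gradient: float = 0.0
    heavy_tail_cm: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_subjects, self.k_true, self.n_cm_info,
                  self.n_cm_noise, self.n_pbm_signal, self.n_pbm_null)
        if any(c < 0 for c in counts):
            raise ConfigError("all counts must be >= 0")
        if self.n_subjects == 0:
            raise ConfigError("need at least one subject")
        if self.n_cm_info + self.n_cm_noise == 0:
            raise ConfigError("need at least one CM variable")
        if self.k_true < 1:
            raise ConfigError("k_true must be >= 1")
        for p in (self.dx_noise, self.missing_rate_base,
                  self.missing_dx_gradient):
            if not 0.0 <= p <= 1.0:
                raise ConfigError("probabilities must lie in [0, 1]")
        if self.effect_size < 0:
            raise ConfigError("effect_size must be >= 0")
        if self.pbm_effect_size is None:
            self.pbm_effect_size = self.effect_size

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        import yaml
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class GroundTruth:
    """What the generator planted, for oracle checks downstream."""

    cluster_of_subject: pd.Series          # subject id -> 1..k_true
    informative_cm_ids: set = field(default_factory=set)
    signal_pbm_ids: set = field(default_factory=set)
    #: per signal pBM, the unordered cluster pairs with a true location
    #: difference, as sorted (a, b) tuples of 1-based cluster labels
    signal_pairs: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "cluster_of_subject": {str(s): int(c)
                                   for s, c in self.cluster_of_subject.items()},
            "informative_cm_ids": sorted(self.informative_cm_ids),
            "signal_pbm_ids": sorted(self.signal_pbm_ids),
            "signal_pairs": {p: sorted(map(list, pairs))
                             for p, pairs in self.signal_pairs.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            cluster_of_subject=pd.Series(d["cluster_of_subject"]).astype(int),
            informative_cm_ids=set(d["informative_cm_ids"]),
            signal_pbm_ids=set(d["signal_pbm_ids"]),
            signal_pairs={p: {tuple(x) for x in pairs}
                          for p, pairs in d["signal_pairs"].items()})


def _directions(rng: np.random.Generator, n: int) -> list[str]:
    """Half higher_worse, half higher_better, in random order."""
    dirs = ["higher_worse"] * ((n + 1) // 2) + ["higher_better"] * (n // 2)
    return list(rng.permutation(dirs))


def generate_cohort(config: GeneratorConfig) -> tuple[Cohort, GroundTruth]:
    """Draw one complete cohort plus its ground truth.

    Bit-reproducible given ``config.seed``.  Missingness is injected
    separately by :func:`inject_missingness` so the complete values stay
    available as an oracle.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, k = cfg.n_subjects, cfg.k_true

    # near-balanced planted clusters, shuffled
    base = np.tile(np.arange(k), n // k + 1)[:n]
    clusters = rng.permutation(base)                       # 0-based
    sev_score = clusters / (k - 1) if k > 1 else np.zeros(n)

    subj = pd.Index([f"S{i:04d}" for i in range(n)], name="subject_id")
    data: dict[str, np.ndarray] = {}
    cat_rows: list[dict] = []

    def cm_noise(size):
        if cfg.heavy_tail_cm:
            return rng.standard_t(3, size=size) / np.sqrt(3.0)
        return rng.standard_normal(size)

    # ---- DX: quintile cut of latent severity + label-shift noise --------
    edges = np.quantile(sev_score, [0.2, 0.4, 0.6, 0.8])
    dx_level = np.searchsorted(edges, sev_score, side="left")
    shift = rng.random(n) < cfg.dx_noise
    step = rng.choice([-1, 1], size=n)
    dx_level = np.clip(dx_level + shift * step, 0, 4)
    data["DX"] = np.array([DX_LEVELS[l] for l in dx_level])
    cat_rows.append({"variable": "DX", "category": "DX",
                     "vartype": "categorical", "direction": "none",
                     "domain": ""})

    # ---- CM block -------------------------------------------------------
    info_names = [f"CM_info_{j:02d}" for j in range(cfg.n_cm_info)]
    noise_names = [f"CM_noise_{j:02d}" for j in range(cfg.n_cm_noise)]
    cm_dirs = _directions(rng, cfg.n_cm_info + cfg.n_cm_noise)
    for name, direction in zip(info_names + noise_names, cm_dirs):
        if name in info_names:
            vals = cfg.effect_size * clusters + cm_noise(n)
        else:
            vals = cm_noise(n)
        if direction == "higher_better":
            vals = -vals
        data[name] = vals
        cat_rows.append({"variable": name, "category": "CM",
                         "vartype": "continuous", "direction": direction,
                         "domain": ""})

    # ---- pBM block ------------------------------------------------------
    sig_names = [f"PBM_sig_{j:02d}" for j in range(cfg.n_pbm_signal)]
    null_names = [f"PBM_null_{j:02d}" for j in range(cfg.n_pbm_null)]
    pbm_dirs = _directions(rng, cfg.n_pbm_signal + cfg.n_pbm_null)
    signal_pairs: dict[str, set] = {}
    for j, (name, direction) in enumerate(zip(sig_names + null_names, pbm_dirs)):
        vals = rng.standard_normal(n)
        if name in sig_names:
            target = j % k                                  # round-robin
            vals = vals + cfg.pbm_effect_size * (clusters == target)
            signal_pairs[name] = {tuple(sorted((target + 1, o + 1)))
                                  for o in range(k) if o != target}
        if direction == "higher_better":
            vals = -vals
        data[name] = vals
        cat_rows.append({"variable": name, "category": "PBM",
                         "vartype": "continuous", "direction": direction,
                         "domain": ""})

    cohort = Cohort(pd.DataFrame(data, index=subj),
                    VariableCatalog.from_records(cat_rows))
    truth = GroundTruth(
        cluster_of_subject=pd.Series(clusters + 1, index=subj, name="cluster"),
        informative_cm_ids=set(info_names),
        signal_pbm_ids=set(sig_names),
        signal_pairs=signal_pairs)
    return cohort, truth


def inject_missingness(cohort: Cohort, config: GeneratorConfig) -> Cohort:
    """Mask cells at probability base + gradient * (subject's DX level).

    The DX column itself is never masked (the diagnosis is recorded for
    every subject; it is the missingness of *measurements* that carries
    diagnostic information).  Returns a new cohort; the input stays
    complete, so the true values remain recoverable for oracle checks.
    """
    dx_var = cohort.catalog.dx_variable
    levels = dx_severity_level(cohort.data[dx_var])
    probs = config.missing_rate_base + config.missing_dx_gradient * levels
    if np.any(probs > 1.0):
        raise ConfigError(
            f"missingness probability exceeds 1 (max {probs.max():.3f})")
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 0x6D697373]))
    masked = cohort.data.copy()
    value_cols = [c for c in masked.columns if c != dx_var]
    mask = rng.random((len(masked), len(value_cols))) < probs[:, None]
    block = masked[value_cols].to_numpy(dtype=float)
    block[mask] = np.nan
    masked[value_cols] = block
    return Cohort(masked, cohort.catalog, dict(cohort.meta))
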