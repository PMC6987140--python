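# Methods

## The model

The 3C strategy treats disease subtyping as a three-stage procedure on a
subject × variable table with a knowledge-driven variable catalog.

**Categorize.** The catalog partitions variables into a single assigned
diagnosis (DX, an ordinal label such as the five-level
CN < SMC < EMCI < LMCI < AD staging), clinical measurements (CM) and
potential biomarkers (pBM). Categorization is an input, never inferred:
the premise of the strategy is that the DX is a crude but informative
surrogate for disease severity, so it is used to *screen* CMs but never
to define the subtypes.

**Cluster.** CMs are screened by two-stage random-forest permutation
importance against DX. Each "forest" is a bag of CART trees with sqrt
feature sampling; the bootstrap is drawn explicitly so out-of-bag (OOB)
membership is exact, and a variable's importance in a forest is the mean
over trees of the increase in OOB error when that variable's OOB column
is permuted. Stage 1 (thresholding) averages importances over
`n_forests_threshold` forests and drops variables whose mean importance
falls below the minimum of a regression-tree fit of the importance
standard deviations against importance rank (the sd plateau of the
irrelevant variables). Stage 2 (interpretation) orders survivors by mean
importance, fits nested forests on the top-1, top-2, … prefixes
(`n_forests_interpretation` forests each) and selects the smallest
prefix whose mean OOB error is within one standard deviation (of the
best prefix's errors) of the minimum. Subjects are then clustered on the
selected CMs by PAM — greedy BUILD initialization followed by
best-improvement SWAP exchanges — under the Manhattan metric, which
keeps medoids as observed patients and is robust to outlying
coordinates. The gap statistic
`gap(k) = E*[log W_k] − log W_k`, with
`W_k = Σ_r D_r / (2 n_r)` over clusters (D_r the within-cluster sum of
pairwise Manhattan distances, both orders) and a uniform-box reference,
advises a candidate range of k; k itself is a required analyst input
because the original design combines the curve with clinical judgment.

**Classify.** Each pBM is tested across clusters with the
Kruskal–Wallis H test (midranks, tie correction, chi-square reference
with k−1 df); BH step-up control at budget q = 0.05 selects S of the M
candidates. For each selected pBM, all k(k−1)/2 cluster pairs are tested
with the two-sample Wilcoxon rank-sum test — exact enumeration when the
pooled sample has ≤ 20 tie-free observations, otherwise the
tie-and-continuity-corrected normal approximation — and, per the
Benjamini–Bogomolov treatment of families examined only after selection,
BH runs within each selected pBM's pair family at the reduced level
q·S/M (a pooled-BH mode over all selected pairs is available behind
`FdrConfig(pooled_pairwise=True)`; the per-family mode is the default as
it matches the selected-family formulation). Rejected pairs are signed
by mean-rank direction.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `k` | required | number of subject clusters (analyst choice) |
| `n_forests_threshold` / `n_forests_interpretation` | 50 / 25 | forests per screening stage |
| `n_trees` | 100 | trees per forest; 100 keeps a 650-subject screen near two minutes on one CPU while the 50-forest average stabilizes importances |
| `q` | 0.05 | FDR budget of the pBM screen; the pairwise stage runs at q·S/M |
| `corr_threshold` / `gini_threshold` | 0.99 / 0.05 | redundancy removal: |r| above / Gini impurity 1 − Σp² below |
| `max_var_missing_frac` | 0.3 | complete-case step drops variables above this missing fraction, then subjects with any gap |
| `B` | 50 | gap-statistic reference draws; s_k carries the √(1+1/B) factor |
| `scale_cms` | off | per-variable standardization before Manhattan distances |
| `level` | 0.95 | binomial order-statistic CI level for cluster medians |

## The synthetic generator

The generator emulates the data regime the strategy was designed for:
`k_true` near-balanced clusters placed along a latent severity axis;
informative CMs with cluster means separated by `effect_size` (in units
of the unit within-cluster sd) and many iid noise CMs; a DX label
produced by a five-level quantile cut of severity plus `dx_noise`
one-level label shifts, so DX overlaps but does not match the clusters;
signal pBMs shifted by `pbm_effect_size` in one designated cluster each
(round-robin over clusters) among exchangeable null pBMs; and
missingness with per-cell probability `missing_rate_base +
missing_dx_gradient × DX level`, reproducing diagnosis-informative
missingness (the DX cell itself is always recorded). Severity directions
are randomized — half the variables run "higher = worse", half
"higher = better" — so the report layer's orientation handling is
exercised, and CM noise can be switched to a scaled t(3) to stress the
rank-based stages.

What it deliberately does not emulate: within-cluster CM correlation
(diagonal covariance; real cognitive batteries are strongly correlated),
mixed variable types in the generated blocks (all generated CMs/pBMs are
continuous; the preprocessing handles ordinal/categorical variables but
the generator does not produce them), cluster-size imbalance, and any
longitudinal structure. Passing recovery tests therefore show the
machinery is correct under the planted-effect model, not that subtypes
of comparable clarity exist in real cohorts.

## Numerical and design choices

- **PAM determinism and restarts.** BUILD and SWAP break ties by lowest
  index. Because best-improvement SWAP occasionally converges to a local
  optimum that only a simultaneous two-medoid exchange could escape, the
  solver additionally runs two seeded random-initialization SWAP passes
  and keeps the lowest-cost solution (BUILD's on ties); the result is
  deterministic given the data order and seed. On instances small enough
  for exhaustive medoid enumeration the implementation attains the exact
  optimum in ≥ 95% of random instances and is always within 5% (asserted
  in the suite).
- **Complete-case order.** Variables are filtered before subjects
  (threshold 0.3): the original workflow's reductions were
  variable-light and subject-heavy, which this order reproduces.
- **Redundancy removal** keeps the earlier variable in catalog order
  (user-controlled, deterministic); zero-variance continuous variables
  are dropped as "constant". Gini impurity applies to discrete variables
  only.
- **Monotone transforms** are selected by |sample skewness| alone from
  {identity, log(x−min+1), √(x−min), rank-normal scores}; the original
  methodology also weighed linearity and variance homogeneity, which is
  documented here as a simplification. Transforms never change ranks, so
  the classify stage is invariant to them.
- **Quantile convention.** Severity quantiles use (midrank − 1)/(n − 1)
  pooled over *all* subjects, so the observed minimum maps to 0, the
  maximum to 1, and cluster medians are comparable on one axis; the
  alternative rank/n convention would leave the endpoints unreachable.
  Variables with direction `none` are excluded from profiles with a
  warning.
- **Median CI.** lower = x₍ₗ₎ with l the largest integer whose
  Binomial(n, ½) CDF at l−1 is ≤ (1−level)/2; upper symmetric. The
  endpoints are observed order statistics; coverage is ≥ nominal by
  construction and is property-tested at n = 25 over 2000 replicates.
- **Leaf ordering.** Dendrogram leaf orders (variable similarity,
  heatmap rows/columns) orient every merge by the lexicographically
  smallest leaf profile, making the ordering invariant to input
  permutation up to total reflection.
- **Gap reference** is the uniform distribution over the per-feature
  range box (the simple reference); a PCA-aligned variant was considered
  and not implemented — the curve is advisory here and the simple
  reference keeps it metric-consistent and fast.
- **k candidates from the gap curve** follow the drop rule (first
  through second k where the gap decreases); with fewer than two drops
  the classical one-standard-error rule is returned as a singleton.
- **Screened CMs enter Manhattan distances unstandardized** by default
  (`scale_cms` toggles per-variable scaling): the screening stage
  already restricts to DX-relevant variables, and the original analysis
  does not document scaling.
- **Degenerate inputs**: constant vectors give H = 0/p = 1 in KW,
  identity/"degenerate" in transforms, all-0.5 quantiles with a warning;
  clusters with < 2 subjects make their pairs untestable (sign 0, p
  absent) rather than failing the run.

## Problem sizes used by the suite

Monte-Carlo checks run at sizes chosen to make their targets
near-certain under the planted effects while keeping the default suite
fast: screening recovery uses 20 cohorts of 400 subjects (5 informative
among 55 CMs, effect 3) with 8/15 forests of 50 trees — forest counts
below the 50/25 defaults trade a little importance stability for speed,
which the pass criterion (≥ 4/5 informative, ≤ 2 noise in ≥ 18/20)
absorbs; the full-scale recovery check runs one 650-subject, k = 6
cohort at the full 50/25/100 defaults; FDR control uses 500 replicates
of the 300-subject, 4-cluster, 20 + 150 pBM configuration; gap-statistic
behaviour uses 90-point three-blob data with B = 50 over 20 seeds.

## Known limitations

- The interpretation step selects a minimal *predictive* prefix; when
  informative CMs are mutually redundant it may legitimately stop before
  including all of them. The original method's optional third
  ("prediction") step is not implemented.
- k is never chosen automatically; `choose_k_candidates` is advisory.
- No imputation is offered by design (missingness is treated as
  informative), so heavy missingness shrinks the complete-case cohort.
- Exact reproduction of the originally reported selected variable sets
  requires the restricted cohort and the original forest seeds; only the
  procedure and its printed procedural constants are reproducible.
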