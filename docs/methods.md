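# Methods

This note documents the statistical models, numerical choices, and
limitations behind `mbcca`.

## Data model

All stages exchange a validated samples × features `FeatureTable` of
finite non-negative doubles with a `value_kind` tag (`count`, `rpk`,
`normalized`, `log2`). The tag is advisory: arithmetic never branches
on it, but writers set it so provenance survives round trips. Feature
ids for per-organism genes use the composite `gene|taxon` convention of
HUMAnN3-style exports; a splitter derives taxon labels when explicit
feature metadata is absent. TSV is the only interchange format —
simple, diffable, and what ASV/gene-table exporters emit. Validation
(duplicate ids, ragged rows, missing/non-numeric/negative cells, each
with its own error type naming the location) happens entirely at read
time, so computation stages can assume clean input.

## Diversity

Alpha indices use the classical plug-in forms on within-sample relative
abundances. Shannon entropy uses the natural log by default with a
`base` option, since published values vary by convention. Chao1 uses
the bias-corrected form S_obs + F₁(F₁−1)/(2(F₂+1)), which remains
defined with no doubletons; it requires integer counts because
singletons are literal count-1 observations. Bray–Curtis is computed
on the values as provided — no internal rarefaction or normalization;
any library-size correction is the caller's responsibility upstream.
A pair of all-zero samples has an undefined Bray–Curtis ratio and is
assigned distance 0 (identical emptiness).

PCoA is classical metric scaling: eigendecomposition of the
double-centered −d²/2 matrix. Bray–Curtis matrices are generally
non-Euclidean, so negative eigenvalues occur; they are retained in the
reported spectrum (so the practitioner can see the distortion) but
excluded from coordinates, and explained proportions are taken relative
to the positive part of the spectrum.

ANOSIM ranks all n(n−1)/2 pairwise distances (average ranks on ties)
and reports R = (r̄_between − r̄_within)/(M/2). Significance uses the
add-one permutation estimator p = (1 + #{R_perm ≥ R_obs})/(n_perm + 1)
under seeded label permutation, which is never zero and is exact in
expectation under exchangeability. Pairwise mode reports both raw and
BH-adjusted p-values, since conventions differ between publications.

## Differential features

Group comparisons use the two-sided Wilcoxon rank-sum test: exact
enumeration when n₁+n₂ ≤ 12 with no ties, otherwise the tie-corrected
normal approximation with continuity correction. A feature constant
across the pooled samples carries no rank information and gets p = 1.
Each comparison within one data layer forms a single
Benjamini–Hochberg family; direction is the sign of the group-median
difference — robust, and consistent with a rank-based test — with
`none` when medians tie.

Taxon-specific scaling renormalizes each organism's genes within each
sample to a fixed total (default 10⁶, a within-taxon CPM analogue), so
gene abundance is interpreted relative to that organism's total
transcriptional activity rather than community composition. Organisms
with zero total in a sample stay zero there. The constant is
configurable; any positive value yields identical downstream rank
statistics.

The amplicon layer is log2(x + pseudocount)-transformed before
integration (pseudocount 1, configurable) because ASV-scale values are
heavily right-skewed with many near-zero entries. Features with at
most one nonzero sample are dropped before correlation analyses — a
single carrier cannot support correlation structure.

The six-module classifier partitions the up/down DEG sets of the day-3
and day-6 comparisons: module 1 up on day 3 only, 2 commonly up, 3 up
on day 6 only, and 4/5/6 the mirrored down modules. Genes up in one
comparison and down in the other do not fit any of the six definitions;
they receive an explicit `discordant` label rather than being silently
dropped, keeping the output a true partition of the input.

## Sparse CCA

The core is the rank-1 penalized matrix decomposition of the
column-standardized cross-product Z = XᵀY: alternating updates
u ← P(Zv), v ← P(Zᵀu), where P soft-thresholds, L2-normalizes, and
bisects the threshold so that ‖·‖₁ ≤ c. This maximizes uᵀZv under
unit L2 norms and L1 budgets — sparse CCA under the identity
within-set covariance approximation, appropriate when p ≫ n makes
within-set covariances unestimable. Numerical choices:

* Penalty parameterized as a fraction f ∈ (0, 1] with c = f·√p on each
  side; one shared f for both matrices. f = 1 deactivates the
  constraint (Cauchy–Schwarz) and the fit provably reduces to the
  truncated SVD — the test suite's oracle.
* Initialization from the leading right singular vector of Z, making
  the fit deterministic; only permutation tests consume the seed.
* Sign fixed so the largest-magnitude entry of u is positive, applied
  before any component matching.
* K components by deflation Z ← Z − d·uvᵀ, which enforces
  uₖᵀZ_deflated vₖ = 0 exactly.
* The bisection in the projection tracks the smallest feasible
  threshold; when tied maxima make no threshold feasible (the c → 1
  limit), the projection returns the single largest-magnitude
  coordinate, lowest index on ties.
* `pmd_rank1` stops when the largest iterate change drops below `tol`
  (default 1e-6). `scca_fit` passes `tol=1e-12` down: deflation error
  is first-order in the iterate error, so a looser tolerance would
  visibly corrupt later components' singular values.
* Zero-variance columns are dropped with a logged warning before
  standardization.

Per component the reported canonical correlation is the Pearson
correlation of the projected scores Xu and Yv.

**Penalty tuning** scores each grid value (default 20 equally spaced
values on [0.02, 0.5]) by leave-one-out cross-validation: refit on
n−1 samples, project the held-out sample with the refit weights
(components matched to the full fit by maximal |cosine| and
sign-aligned), and correlate the n held-out score pairs; the score is
the mean over components. In-sample canonical correlation is
non-decreasing in f and would trivially select the largest penalty, so
cross-validation is the only meaningful reading of "best average
correlation". Ties resolve to the smallest (sparsest) penalty.

**Permutation significance** refits all K components after permuting
the sample order of Y (column standardization is permutation-invariant,
so the standardized matrix is permuted directly). Refitting — rather
than reusing fixed weights — makes the null account for selection
optimism. Per-component p-values use the add-one estimator and are BH
adjusted across the K components.

**LOOCV extraction** calls a feature robust when its weight is nonzero
in at least a retention fraction (default 1.0) of the n leave-one-out
refits, after cosine matching; robust sets are intersected with the
full-fit support so they are always subsets of the selected sets.

K defaults to min(n−1, 10) and is configurable; there is no principled
automatic choice, and reported component counts in comparable analyses
vary by data layer.

## Association networks

Within each group's samples, all feature pairs are tested with Spearman
correlation (average ranks; p from the t-distribution approximation,
standard at the n ≈ 5–15 per group this design produces; the exact
permutation null appears only as a test oracle). Edges require
p < 0.05 and ρ ≥ 0.5. The signed filter is the default reading of the
threshold; an `absolute` mode is provided because negative
host–microbe associations are biologically meaningful. Edge weight is
−log10 p (p capped at 1e-300 so weights stay finite when the
t-approximation underflows at |ρ| = 1).

Communities come from deterministic greedy modularity maximization
(CNM). This replaces GUI-plugin community detection deliberately: the
reproducible surface is the modularity value and behaviour on separable
graphs, not label-for-label agreement with any particular tool.
Centralities are degree, unnormalized shortest-path betweenness (each
unordered pair counted once; normalization is rank-invariant within one
network and switchable off-the-shelf), and neighborhood connectivity
(mean neighbor degree, 0 for isolated nodes). Because "high
neighborhood connectivity" is a qualitative criterion, hubs are defined
operationally: nodes with degree ≥ 2 whose neighborhood connectivity
reaches the 0.90 quantile among such nodes, boundary ties included —
both knobs configurable and recorded in the run manifest.

The gene-family extractor restricts to edges joining a flagged node
(e.g. `is_aaRS`) to a host gene, annotates host genes with a
user-provided two-column gene → GO table (no ontology traversal), drops
terms annotating ≥ 100 genes (small terms carry interpretable signal),
and reports per (microbe, term) the distinct host-gene count and mean ρ.

## Synthetic data

`simulate_paired_omics` draws shared latent scores Z ~ N(0, I) and
builds X = Z·diag(s)·Aᵀ + E with sparse equal-magnitude random-sign
unit-norm loading columns and i.i.d. Gaussian noise. The amplitude
s = σ·√(r/(1−r)) makes the population correlation of the true
projections equal the requested strength r exactly, so recovery tests
have a calibrated target. Columns are shifted to be non-negative —
harmless, since every downstream analysis centers or ranks. Counts
come from a log-normal → Poisson hierarchy (feature-level log-normal
baselines, per-cell log-normal dispersion with sd 0.5, Poisson
sampling); planted features multiply their non-reference group means by
2^(±effect). These are the simplest forms consistent with the
pipeline's rank-based tests, which are insensitive to the marginal
distribution. The composed study (three groups of five samples,
60 taxa with 14 planted differential, six organisms × ten genes with
three aaRS each, 120 host genes covering all six DEG modules, plus one
latent factor coupling a subset of differential taxa to host DEGs)
mirrors the scale of a small in-vivo time course.

What the generators do **not** emulate: phylogenetic correlation among
taxa, compositional (closed-sum) constraints, sequencing-depth
variation, zero inflation beyond the Poisson, and batch structure.
Passing recovery tests therefore demonstrates correctness of the
estimators under their own assumptions, not robustness to every
real-data pathology.

## Problem sizes in tests and the acceptance script

Simulation-based checks use the smallest sizes that remain
statistically meaningful: calibration of the sparse-CCA permutation
test uses 200 independent 30 × (15, 15) datasets with 99 permutations;
ANOSIM null calibration uses 500 datasets of 12 samples; loading
recovery uses n = 200 with 200 features per side over 5–10 seeds; the
end-to-end acceptance run uses the default synthetic study with an
8-value penalty grid, 199 permutations, and K = 4 components. These
are the package's reference problem sizes; all scale linearly if
increased.

## Known limitations

* The within-set covariance is approximated by the identity (PMD);
  strongly correlated predictors within one layer can split weight
  across correlated features.
* Spearman p-values use the t-approximation even at very small n,
  where it is slightly anti-conservative; the edge filter's ρ ≥ 0.5
  requirement dominates in that regime.
* Greedy modularity maximization has a resolution limit on very small
  or very dense graphs.
* The six-module classifier takes DEG sets as given; it does not model
  uncertainty in the upstream differential calls.
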