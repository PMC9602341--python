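# Methods

This note documents the models, estimators and numerical choices behind
`micronet`, and what the synthetic-data tests do and do not establish.

## Study design emulated

The pipeline is built for dense community time series under two temperature
regimes: triplicate cultures per condition, 30 samples per replicate at
0.5-day intervals, observed by 16S amplicon sequencing (genus-level
proportions) plus qPCR totals corrected by a spike-in internal standard
(default 1e7 copies of artificial DNA per sample).  Per condition that
yields 90 samples; removing the day-0 sample of each replicate (initial
transient) leaves 87.  Genera absent — zero estimated absolute abundance,
i.e. zero reads — at more than 40 of those 87 pooled time points are
excluded from network inference.  Absence is counted on the pooled points
across replicates, and no pseudocount is added at this stage: read-level
zeros are the only observable absence.

## Synthetic community generator

Latent dynamics follow a stochastic multispecies Ricker map,

    N_i(t+1) = N_i(t) · exp( r_i + Σ_j a_ij N_j(t) / K + ε_it ),
    ε_it ~ Normal(0, σ²),

a discrete-time generalized Lotka-Volterra analogue chosen over an ODE
because it matches the 0.5-day sampling grid and keeps the causal
structure aligned with the lag −1 convention of the causality test.
`k_scale` (K) sets the abundance scale of density dependence; with
a_ii = −r_i a genus alone equilibrates at N = K.  Replicates share
parameters and differ only in initial conditions (lognormal) and noise.
Trajectories exceeding an overflow cap raise an explicit divergence error.

The default two-regime scenario has 18 genera, ~20% of ordered pairs
interacting, 70% of interactions positive, intrinsic rates r ~ U(1.8, 2.3)
per step, process noise σ = 0.05.  Positive coupling magnitudes
(U(0.03, 0.15)) are deliberately weaker than negative ones (U(0.1, 0.4)):
in an exponential-growth map, mutualistic positive feedback at competitive
magnitudes drives unbounded blow-up, which real bounded communities do not
show.  The stress regime multiplies growth rates by 1.3 (metabolic
speed-up with temperature) and negative off-diagonal couplings by 2.0
(intensified competition when supply cannot meet faster growth).  These
regime factors encode the hypothesized mechanism — they are not fitted to
any measured data set, so regime contrasts in the synthetic experiment are
qualitative, not quantitative, statements.

The observation model draws read counts as Multinomial(depth, latent
proportions) at 100,000 reads/sample, and reports
`total = true_total · efficiency_true · qPCR-noise / efficiency_estimated`,
where the efficiency estimate comes from the recovered spike-in with its
own qPCR noise (both noises lognormal; efficiency mean 0.7, CV 0.1; qPCR
CV 0.05).  Not modeled: sequence-level reads, PCR/primer bias, chimeras,
taxonomic misassignment, or compositional zero-inflation beyond the
multinomial.  Passing tests therefore show the inference machinery is
sound under multinomial sampling and multiplicative total noise — not that
it is robust to amplification bias in real surveys.

A three-genus chain scenario (g00 → g01 → g02, competitive couplings 0.4,
chaotic rates r = 2.9, σ = 0.02) is the benchmark for directed-edge
recovery; information flows one way only, so reverse and indirect pairs
measure the false-positive behavior.

## State-space reconstruction and simplex projection

Series are z-scored per genus over the concatenated replicates of one
condition (population SD); constant series are rejected.  Delay blocks
never mix time points from different replicates: any row needing a lag
before a replicate's start, or a target beyond its end, is masked invalid.

Simplex projection forecasts each valid row from its k nearest valid
neighbors (Euclidean metric; k = E + 1), excluding the row itself and
same-time rows from other replicates — replicate copies of the same moment
would leak the answer.  No additional Theiler window is applied (the
series are short; documented trade-off).  Weights are
w_j = exp(−d_j / d_min) with d_min the nearest-neighbor distance, so they
depend only on distance ratios; at d_min = 0 the zero-distance neighbors
vote with equal weight.  Distance ties break deterministically by row
index.  `select_embedding` picks E (default grid 1..10) by leave-one-out
forecast correlation, ties toward smaller E.  On short stochastic series
the k = E + 1 convention mildly favors larger E (more neighbors average
more noise), which is why the embedding grid for the pair test defaults to
1..5 on 29-point replicates.

## Causality test

Edge X→Y ("X causes Y", one 0.5-day step) is tested by cross-mapping: if X
forces Y, Y's delay embedding encodes X, so Y-coordinates can recover the
lagged cause.  Two leave-one-out simplex models forecast X at t−1:

* full    — Y at lags {0, −1, ..., −(E_f−1)}  (includes the candidate Y_t)
* reduced — Y at lags {−1, ..., −E_r}         (only strictly lagged info)

The statistic is te = ln MSE_reduced − ln MSE_full, a log information-flow
proxy; te > 0 iff the time-t coordinate improves recovery of the lagged
cause.  Both models keep the same number of coordinates at a given E and
each selects its own dimension by its own cross-map skill, evaluated on a
common prediction-row set (rows valid at the deepest grid dimension).
This dimension-matched, best-vs-best comparison is essential: a naive
nested comparison (full = reduced + one extra coordinate) rewards model
capacity itself and mis-calibrates the test — measured on independent
series it roughly doubled the nominal false-positive rate.

Significance: prediction-target indices are resampled with replacement
B = 2000 times; p = (1 + #{te* ≤ 0}) / (B + 1); an edge requires p < α
(default 0.05, no multiple-testing correction by default, a
Benjamini–Hochberg mode is available) and te > 0.  The same bootstrap
seed is used for every pair so edge decisions are invariant to relabeling
the genera.  A circular-shift surrogate test (shift ≥ E within replicate,
applied to the candidate coordinate only, model dimensions frozen) is
provided as an independent cross-check.  Only lag −1 is tested by
default, to limit indirect-path detections.

Measured calibration under the defaults: on 300 independent-series trials
P(significant) ≈ 0.067 at α = 0.05; on 50 chain-scenario runs the true
edges are recovered at TPR ≈ 0.9 with FPR ≈ 0.06.

## Regularized S-map

For a detected edge X→Y, Y_t is regressed on Y's own lags −1..−E (E from
the causality test) plus X at lag −1, with a locally weighted ridge fit at
every prediction time: weights w_k = exp(−θ d_k / d̄) (d̄ = mean library
distance), objective Σ w_k (y_k − b0 − b·z_k)² + λ‖b‖², intercept
unpenalized, solved by the normal equations with the target row excluded
from its own library.  θ = 0, λ = 0 reduces to global least squares.
Hyperparameters are tuned by leave-one-out MSE over grids
θ ∈ {0, 0.5, 1, 2, 4, 8}, λ ∈ {0, 0.01, 0.1, 1}; ties toward smaller θ,
then smaller λ, independent of grid order.  Ridge (pure L2) was chosen
over elastic-net variants to keep a closed-form deterministic solve.

The edge strength is the arithmetic mean over prediction times of the X
coefficient (standardized units); its sign is the edge sign.  A mean of
exactly zero is flagged indeterminate and excluded from signed summaries.
Causes are embedded one at a time (matching the pairwise causality test);
a joint embedding of all significant causes per effect is a possible
extension, not the default.  On a linear stochastic three-species system
(n = 300, noise SD 0.05) the time-averaged coefficients recover the true
Jacobian entries to within 0.15 absolute error.

## Network statistics

Connectance is L / (S(S−1)) over directed interspecific links — the
denominator excludes self-links, which reproduces the published ratios
from published counts.  Genera passing the prevalence filter remain nodes
even when no edge is significant.  Pair states follow the two directed
signs: (+,+) mutualism, (+,0) commensalism, (+,−) antagonism, (−,0)
amensalism (also accepted under the spelling "amenalism"), (−,−)
competition; percentages are over pairs with at least one link.  Percent
decreases are computed on unrounded values.  The cross-condition graph
correlation is the Pearson correlation of the vectorized off-diagonal
binary adjacencies of the two common-genus subnetworks (sign information
excluded; an absolute-strength weighted variant is available).  Wilcoxon
rank-sum tests use exact enumeration for tie-free groups of ≤ 10,
otherwise the tie-corrected normal approximation.  Bray-Curtis
dissimilarity, the rank-sum test, and rank/product-moment correlations are
delegated to scipy; Bray-Curtis is computed on raw (unscaled) genus
abundances.

## Orchestration and reproducibility

A single run seed fans out to per-stage seeds through fixed
`SeedSequence(seed, spawn_key=(offset,))` children collapsed to 31-bit
integers, so each stage is independently reproducible and a full re-run
with the same seed is byte-identical (the manifest records the stage
seeds and configuration, not the output path).  Test-suite problem sizes
— 18-genus default runs, 50 chain replicates, 300 null trials with
B = 500 bootstrap resamples — were chosen so the full suite completes in
about a minute on one CPU while keeping the Monte-Carlo margins of the
calibration checks comfortable.

## Known limitations

* The generator's regime factors are mechanistic postulates; no
  quantitative correspondence with any measured total-abundance curve is
  claimed or calibrated.
* At 87 points per condition the causality test has limited power for weak
  couplings; the default 18-genus scenario detects only a minority of the
  generating interactions (signs of detected edges are, however, reliable).
* The lag −1 restriction suppresses but does not eliminate indirect-path
  detections in chains.
* Nonmetric multidimensional scaling ordination is out of scope; only the
  Bray-Curtis trajectory is provided as the stress diagnostic.
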