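# Methods

This note records the models implemented in `pteroevo`, the numerical
choices behind them, what the synthetic-data generators do and do not
emulate, and the design decisions taken where more than one reasonable
convention exists.

## Trait models and likelihoods

All models treat the tip vector of mean condylobasal lengths (CBL, mm) as
multivariate normal on a rooted, dated phylogeny (branch lengths in Myr).
The mean and covariance are accumulated branch by branch, which lets one
code path serve the whole family:

* **BM** — Brownian motion with rate σ² (mm²/Myr) and root state z0.
  Covariance entry (i, j) is σ² times the shared root-to-MRCA path length.
* **BMS** — Brownian motion with a separate rate per selective regime;
  per-branch rates are summed along shared paths.
* **EB** — early burst: rate σ₀²·e^{r·s} with s = time since the root and
  decay r ≤ 0.
* **OU1 / OUM / OUMV / OUMA / OUMVA** — single- and multi-optimum
  Ornstein–Uhlenbeck (Hansen) models. Writing A(t) for the cumulative
  integral of α along a lineage, each tip's expectation is the root state
  discounted by e^{−A} plus regime optima weighted by discounted residence
  times (the weights sum to one); the covariance of tips i and j is the
  variance accumulated along their shared path, discounted by
  e^{−(A_i − A_m) − (A_j − A_m)} where m is their MRCA. With a single α on
  an ultrametric tree this is σ²/(2α)·e^{−α d_ij}(1 − e^{−2α s_ij}).

The root is fixed (no stationary root variance). Under the default
`root_mode="stationary"` the root state equals the optimum of the regime
painted on the root and is **not** a free parameter; `"estimated"` adds z0
as one parameter for sensitivity analysis. The regime of a branch is the
category of its child node; internal nodes carry one painted category
(default M), and fits are typically swept over S/M/L paintings because the
painting is a modelling hypothesis, not data.

Parameter counts for AICc (stationary root): BM 2, EB 3, OU1 3, BMS R+1,
OUM R+2, OUMV/OUMA 2R+1, OUMVA 3R for R regimes. With n = 56 these counts
make the published log-likelihood and AICc columns of the five-model
comparison mutually consistent to ±0.02, which is how the convention was
fixed. The σ reported in that comparison is interpreted as σ², the rate
parameter of the Gaussian increments.

### Numerics

* Covariances are assembled from a per-node recursion for the discounted
  accumulated variance H(v) = e^{−2A(v)}·G(v) (H is bounded by the
  stationary variance, so large α never overflows), and factorized by
  dense Cholesky. Zero-length internal branches (resolved polytomies)
  leave the tip covariance positive definite; a genuinely singular
  covariance raises an error rather than being regularized.
* Fitting profiles everything that is linear or scale-like: the mean
  coefficients (z0 or θ) by GLS, and a single σ² in closed form
  (ML convention, divisor n). What remains is a 1-D search over α (or r)
  done by a deterministic grid plus bounded Brent — this makes OU1/OUM/EB
  fits deterministic without restarts — while the multi-rate models
  (BMS, OUMV, OUMA, OUMVA) use L-BFGS-B from a nested-model start plus
  seeded Latin-hypercube restarts. Bounds: α ∈ [1e-6, 100] /Myr,
  σ² ∈ [1e-8, 1e6], r ∈ [−10, 0].
* θ standard errors are the conditional GLS covariance at (α̂, σ̂²), not
  full-information errors; this matches how optimum uncertainties are
  conventionally reported for Hansen fits.
* A BMS rate estimated at the lower bound is reported as 0 with a boundary
  flag. A constant trait yields a flagged degenerate fit at the σ² lower
  bound rather than a silent divergence.
* Tests compare every model's likelihood against an independent dense
  oracle that propagates the full joint node covariance through the
  per-branch linear-Gaussian transitions and evaluates the density with
  scipy; agreement is required to 1e-8.

## Regime assignment

Categories are assigned from sympatry and relative size, area by area:

* three co-occurring species are ranked S/M/L;
* two species are labelled by membership in global size-tercile bands
  (computed from the span of all sympatric species' means); a same-band
  pair is split into adjacent bands when its gap reaches a threshold
  (default 5% of the global range), and left sharing the band otherwise —
  genuine size overlap does occur and should not be hidden;
* four or more species are labelled by band membership, falling back to
  rank terciles if all share one band;
* a widespread species takes its modal per-area label; modal ties raise an
  error unless `tie_break="prefer_middle"` is given, because such ties
  were resolved by judgment in curation and judgment should be an explicit
  input;
* species alone in all their areas go to M under the three-category scheme
  or to their own I category under the four-category scheme.

Species with size and distribution data but no tip in the tree
("context-only": recently extinct or unsequenced taxa) participate in
per-area banding but never enter a likelihood. The exact numeric rule for
two-species areas is a declared reconstruction — the source procedure is
described in prose only — and is therefore configurable.

The random-regime null (`random_regime_null`) refits the multi-optimum
model under reshuffled tip categories. The default `permute` mode
preserves observed category counts (the stricter null); `uniform` draws
each tip independently. Internal paintings are untouched.

## Signal statistics

* **Pagel's λ** multiplies the off-diagonal covariance; the ML estimate is
  profiled on [0, λ_max], with λ_max found by bisection on positive
  definiteness and always reported. Likelihood-ratio tests against both
  λ = 0 and λ = 1 are returned, since either can serve as the null.
* **Blomberg's K** uses the closed-form ratio of observed to BM-expected
  MSE₀/MSE; on an equal-branch star tree K = 1 exactly. The permutation
  test shuffles tip values and compares the variance of phylogenetically
  independent contrasts (lower variance ⇒ signal), with the add-one
  convention p = (1 + #{perm ≥ observed})/(1 + n_perm) so p is never 0.
  Default n_perm = 999, configurable (resolution below ~1e-3 needs more).
* **Pagel's δ** is a power transform of node depths, rescaled to preserve
  the total depth (entry t → T·(t/T)^δ). The search interval defaults to
  [0.01, 3]; a boundary hit is flagged rather than hidden, because δ
  piling up at the customary upper bound is itself informative (disparity
  concentrated within recent clades).

All three statistics are affine-invariant. To make the *numerical*
estimates share that invariance, the trait is standardized internally
before profiling and the profile optimum is polished by root-finding on a
central-difference score, which resolves the estimate about two orders of
magnitude more finely than function-value minimization alone.

## Ancestral states and change accounting

Internal-node estimates are the GLS conditional expectations under BM; the
REML and ML variants share the point estimates and differ only in the rate
convention for intervals (divisor n−1 from contrasts versus n). Interval
variances include the root-uncertainty term
(1 − c'C⁻¹1)²/(1'C⁻¹1). Per-species change is computed against the
reconstructed state of the species' direct parent node (the most natural
reading of "most recent ancestor"; an MRCA-of-clade variant could be
swapped in). The 5% reporting threshold for "substantial" change is a
config constant. Whether changes are computed on raw or log CBL is an
option; raw is the default.

## Disparity through time

Clade disparity is the average squared pairwise difference of tip values
(equal to twice the sample variance), relative to the whole-tree value; at
each internal-node time the curve averages over all lineages crossing that
time, so it starts at 1 at the root. The null simulates BM at the ML rate
(default 1000 simulations). MDI is the signed area between the observed
curve and the pointwise null median, with both curves closed at (1, 0).
Because the tail convention for MDI p-values is ambiguous in the
literature, both one-sided add-one p-values are reported (`p_ge` for
late-disparity excess, `p_le` for the opposite tail).

Per-population dispersion is the sample coefficient of variation
(sd/mean, divisor n−1) per taxon × island; groups with fewer than two
specimens are reported as missing, never as zero.

## Synthetic data

The generators emulate the study conditions: Yule trees conditioned on the
tip count (default 56) and rescaled to an exact crown age (default
8.7 Myr); traits evolved by exact per-branch Gaussian transitions under
BM, EB, or OU with regime-dependent optima at the fitted scale (defaults
α = 0.60 /Myr, σ² = 52.0 mm²/Myr, θ = 93.4/65.1/47.5/54.4 mm, ancestral
size 55.6 mm for the neutral models); and island communities of 1–5
species assembled either with planted size displacement (pairwise gaps of
at least `min_gap`, default 8 mm, each taxon in one area) or at random
from the full pool. Per-specimen records add i.i.d. Gaussian measurement
noise around the species value.

What the generators do **not** emulate: extinction (no birth–death trees),
fossil/extinct sampling, island-area effects on size, gene-tree
uncertainty in the chronogram, or correlated sampling effort across
islands. Passing tests therefore demonstrate the internal correctness and
calibration of the methods under their own assumptions — not that those
assumptions hold for any empirical dataset.

All generators are bit-reproducible: each operation draws from a stream
derived from the master seed as `SeedSequence(seed, spawn_key=(STREAM,))`,
so adding one simulation never perturbs another.

## Study sizes used in tests

Deterministic examples run on 3–10-tip trees. Stochastic calibrations use
the scales at which their Monte-Carlo standard errors make the assertions
meaningful: optimum recovery uses 100 replicates on the 56-tip tree; the
random-regime null uses 20 experiment repetitions of 100 permutations; λ
calibration uses 200 replicates on a 100-tip tree; MDI calibration uses
120 Brownian replicates with 200 null simulations each and 100 late-burst
replicates; ancestral-root calibration uses 300 replicates. Assertion
windows are expressed in Monte-Carlo standard errors computed from the
replicates themselves, so they adapt to the replicate counts. Brownian
calibration runs place the root state at 200 mm so that excursions at the
fitted rate stay clear of the trait table's positivity bound; the
statistics asserted are location- and scale-invariant, so this does not
affect what is being tested.

## Known limitations

* No measurement-error (per-species SE) term in the likelihoods; species
  means are treated as exact.
* No OU-based ancestral reconstruction; change accounting uses BM states.
* Regimes are hypothesis-driven or random, never searched for (no
  SURFACE/bayou-style reversible-jump machinery).
* The multi-α variants (OUMA, OUMVA) can be weakly identified on trees of
  this size; convergence flags and restart counts are reported and should
  be inspected before interpreting their estimates.
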