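# Methods

## Model

For a binary web `A` (rows consumers, columns resources, diagonal kept
— cannibalism is legal data), the probabilistic niche model assigns
each species a niche position `n ∈ [0, 1]`, and each consumer a diet
centre `c ∈ [0, 1]` and feeding range `r > 0`.  The link probability is
Gaussian in niche distance,

    P_ij = a · exp(−((n_j − c_i) / (r_i / 2))²),

and the fit maximizes the Bernoulli log-likelihood summed over all S²
entries.  Any unimodal kernel would do in principle; only the Gaussian
is implemented.

**Parameterization of `r`.**  `r_i` is a *full width*: the half-width
`r_i/2` is the distance at which the feeding probability falls to
`a/e`.  This keeps `r` commensurate with the deterministic niche
model's diet interval of width `r` centred at `c`, so fitted ranges are
directly comparable with the generative model's.  Other conventions
(`r` as a standard deviation) only rescale fitted ranges by a constant.

**Numerical floors.**  `a` is a global constant 0.9999, not a free
parameter: at exactly 1 a correctly predicted link would put
`ln(1 − P)` at −∞ for the corresponding non-observation.  All
probabilities are clamped into `[1e−10, a]`; the likelihood
contribution of a floored non-link is O(1e−10), so the floor changes
nothing numerically except keeping lnL finite.  Feeding ranges live in
`[1e−6, 2]`: the upper bound exists because on a unit axis any wider
range is observationally indistinguishable (it fixes the scale gauge),
and the lower bound implements the `r → 0` limit without division by
zero.

**Constraints from the data.**  Rows with zero prey are producers:
`c = 0` and `r` pinned at the floor, forcing their whole row of link
probabilities to the probability floor.  Rows with exactly one prey are
specialists: `r` pinned at the floor, `c` free — the fit drives `c`
onto the prey's `n`, reproducing the single link at probability ≈ `a`.
Pinned coordinates are never proposed by the optimizer.  Parameter
counting for AIC is *nominal* (3S for the full model at S species)
without subtracting pinned producer/specialist entries, which matches
the usual presentation of these models.

**Packed parameter vectors.**  Every variant packs its per-species
blocks (in the order n, c, r, those present) followed by its global
coefficients, so the packed length always equals the nominal count k.
Pinned entries remain in the vector but are inert — the constraint
mask overrides them wherever probabilities are computed.  Coupled
parameters (e.g. `r = r0·exp(r1·c)`) are computed from their source and
clamped into the bounds rather than raising mid-optimization, which
keeps the annealer's state space a simple box.

**Gauge.**  The likelihood is invariant under reflecting the axis
(`n → 1−n, c → 1−c`), so fitted axes are identifiable only up to
orientation.  Full-model fits are re-oriented so that `n` correlates
non-negatively with prey count (big consumers high); variants whose
axis is pinned by body mass or coupling coefficients are reported
as-is.

## Fitting

Simulated annealing with Metropolis acceptance `exp(ΔlnL/T)` and
geometric cooling `T_k = T0·cooling^k`.  Defaults: `T0 = 1`,
`cooling = 0.95`, 200 stages, 50 proposals per free coordinate per
stage, 5 restarts, proposal scale 0.1 of each coordinate's box width.
The first restart warm-starts from a trophic ordering (niche positions
from the normalized trophic-sort rank computed by a damped fixed-point
of "height = 1 + mean prey height", ties by prey count; diet centres at
the mean prey position; ranges at 0.2); subsequent restarts start
uniform-random.  Ties between restarts go to the lowest index, and the
reported lnL is re-evaluated from the returned parameters, so results
are deterministic given the seed.

Proposals are a mixture: with probability 0.10 a uniform redraw of one
coordinate, with 0.05 a swap of two species' entire parameter blocks,
otherwise a reflected Gaussian step on one coordinate.  The swap move
matters: the likelihood landscape's deep traps are *arrangements* of
species on the axis, and single-coordinate steps cannot carry a species
across an occupied region.  With swaps enabled, independent runs on the
same web converge to the same likelihood; without them they scatter
over several lnL units.

A proposal changes at most one row (that consumer's `c`/`r` and any
coupled range) and one column (its `n`) of the probability matrix, so
likelihood deltas are computed incrementally from S-length slices;
global-coefficient moves and swaps fall back to full re-evaluation.
The incremental path is verified against full recomputation in the test
suite.

An exhaustive lattice search (`grid_search_oracle`, budget 10⁷ points)
provides an independent optimum for webs with very few free
coordinates; the annealer is required to agree with it to 0.01 lnL on a
three-species web whose continuous optimum (two producers merged at one
position) lies exactly on the lattice.

## Goodness of fit

`N1 = Σ_{A_ij=1} P_ij` is the expected number of observed links
predicted correctly at the fitted parameters, `f_L = N1/L` the expected
fraction, decomposed per species into prey-side (`f_R`) and
predator-side (`f_C`) fractions; fractions with empty denominators are
reported as missing, never zero, and are never flagged as poorly
predicted.  The expected fraction of all matrix entries correct is
`Σ[A·P + (1−A)(1−P)]/S²`.  For the uniform baseline `P = C` these
reduce to `f_L = C` and `C² + (1−C)²` — at C = 203/841 (the Benguela
dimensions) 24% and 63.4%.  The random model's closed-form maximum is
at `p = L/S²` with `lnL = S²[C ln C + (1−C) ln(1−C)]` and k = 1.

## Diagnostics

Derived ratios `x = r/n` and `c′ = c/n` are reported as missing for
species with `n ≤ 1e−6` (producers at the axis origin).  Distribution
tests are one-sample Kolmogorov–Smirnov: `n` against U(0,1); `r`
against an exponential whose scale β is the sample mean, using the
asymptotic p-value with the scale held fixed (no Lilliefors
correction — the plug-in p is anti-conservative, which is documented
here so results are interpretable); and `c′` against U(0,1) after
excluding species with `c′ > 1` (whatever their number), since only
hierarchically feeding species are comparable with the
uniform-below-the-consumer rule.  The Spearman table covers the ten
standard pairs among (n, c, r, x, c′) and log body mass — log only for
presentation, since rank correlations are invariant to monotone
transforms — with Benjamini–Hochberg FDR control at α = 0.05 and
pairwise deletion of missing entries.  The PCA standardizes complete
(n, c, r) triples and reports eigenvalue fractions of the correlation
matrix.

## Synthetic data

`generate_niche_web(S, C, seed)` draws the classic construction:
`n_i ~ U(0,1)`; `x_i ~ Beta(1, 1/(2C) − 1)` so E[x] = 2C;
`r_i = x_i·n_i`; `c_i ~ U(r_i/2, n_i)` (the slightly relaxed
hierarchy); links wherever `|n_j − c_i| ≤ r_i/2`; the smallest-`n`
species forced basal so constraint handling is always exercised.  The
c-interval support follows the standard construction of the original
generative model.  Webs are exactly interval in n-order and
hierarchical (`c ≤ n`); realized connectance at (S = 29, C = 0.24)
averages just under the target (≈ 0.233 over 200 webs) because diet
intervals are clipped at the axis ends, within the ±0.02 calibration
band checked by the tests.

`generate_pnm_web(params, seed)` realizes every entry as an independent
Bernoulli draw from the Gaussian kernel.  `generate_body_masses`
places log10 mass linearly in `n` (defaults: 1e−12 g at n = 0 spanning
17 decades, lognormal scatter 0.5 decades — the range of a
plankton-to-apex marine web), so the allometric model's normalization
inverts it exactly at zero noise.

`graded_params(S)` is the reference parameter set for recovery
experiments: evenly spaced niche positions, ranges broadening up the
axis (`r = 0.1 + 0.25·n`, echoing the allometric widening of diets),
diet centres at `0.75·n`, lowest 15% of species producers; realized
connectance ≈ 0.2 at S = 20.  The even spacing is deliberate:
i.i.d. parameter draws routinely produce trophically equivalent species
whose axis positions are interchangeable, in which case *no* optimizer
can recover the ordering — the likelihood genuinely does not determine
it.  With graded parameters every consumer's diet is a distinct
interval and the ordering is rigidly identified: fits to Bernoulli
realizations at S = 20 recover the true ordering with |Spearman| ≥ 0.95
across realization seeds, while exceeding the true parameters'
likelihood (the MLE-dominance property).

## What the synthetic studies do and do not show

Passing recovery tests on generated webs shows the estimator and
optimizer work when the data-generating process *is* the model with an
identifiable configuration.  Real webs add everything the generator
omits: non-interval diets, uneven taxonomic aggregation, sampling
error in link detection, and trophically equivalent taxa — precisely
the situations where fitted positions are least determined.  Fitted
parameters for near-duplicate species should be read as one
arrangement among equally likely ones.

## Problem sizes and tolerances

Test and acceptance runs use S = 3 for oracle comparisons (lattice
resolution 0.05, ~4×10⁶ points), S = 20 webs with 100-stage,
10-restart fits for recovery, 200 webs for generator calibration, and
2000 null replicates at m = 29 for the K-S type-I check.  These sizes
make every statistical check decisive (Monte-Carlo SEs well inside the
asserted bands) while a full suite run stays in minutes.  Annealer
agreement with the grid oracle is asserted at 0.01 lnL; recovery at
|Spearman| ≥ 0.9; generator calibration at ±0.02 connectance.

## Known limitations

- Only the Gaussian kernel; no per-species peak probability.
- No gradient-based or Bayesian estimation, and no confidence
  intervals on fitted parameters.
- The minimum potential niche model appears only as published
  comparison constants in output tables; it is not implemented.
- Annealing hyperparameters are heuristics sized to ~90-parameter
  problems; very large webs will need longer schedules.
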