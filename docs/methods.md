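# Methods

## Problem and model

A heterogeneous tissue sample contains unknown numbers of cells
N = (N_1, …, N_n) from n known cell lines.  Each cell contributes
additively to m measurable attributes (in the motivating assay: total red,
green and blue fluorescence of a well).  The only measurement taken from
the mixture is the aggregate attribute vector E_sum — the per-attribute sum
over all cells — which is cheap because no single-cell imaging or
segmentation is needed.

The expensive step is done once per cell line, in isolation: p single-cell
measurements give the sample mean μ̂_ij and Bessel-corrected sample SD
σ̂_ij of each attribute j for line i (`cellmix.profiles`).  These profiles
are assumed stable between the profiling experiment and the mixture
measurement; the model has no term for drift, and inconsistent experimental
conditions between the two phases translate directly into biased count
estimates (see Limitations).

With N_i cells of line i, line i's contribution to attribute j is a sum of
N_i i.i.d. single-cell values, so for the cell lines that matter (large
N_i) the central limit theorem gives

    E_sumj | N ≈ Normal( Σ_i N_i μ_ij ,  Σ_i N_i σ_ij² ),

independently across attributes.  This Gaussian approximation is the whole
likelihood (`cellmix.likelihood`); it is agnostic to the single-cell
attribute distribution, which is what makes the attribute choice free.
Cells are assumed not to alter each other's attribute values.

Counts carry independent flat priors on [0, M].  The posterior of each
component given the rest is known only up to its normalizing integral, so
the model is sampled rather than solved.

## Sampling and point estimation

`cellmix.sampler` runs Metropolis-within-Gibbs: each sweep updates every
component once in index order, proposing N_i* ~ uniform(N_i − δ_i, N_i + δ_i)
and accepting with probability min(r, 1), where r is the ratio of
unnormalized posteriors.  Because the prior is flat, r is a pure likelihood
ratio and is exactly independent of M (asserted bitwise in the tests).

Numerical choices:

* **Support floor.**  Counts live in [ε_N, M] with ε_N = 10⁻³ cells, so the
  likelihood variance Σ N_i σ_ij² stays positive even when all but one
  component sits at the boundary.  The floor is a numerical device, not a
  statistical correction; with truly absent lines the marginal posterior
  piles up against it.
* **Out-of-support proposals** are rejected (r = 0) instead of reflected,
  preserving proposal symmetry without Jacobian corrections.
* **δ adaptation.**  δ_i defaults to per-component adaptation during
  burn-in only: every 100 sweeps δ_i doubles if the recent acceptance
  fraction exceeds 0.5 and halves below 0.3, then freezes, so the retained
  chain is a valid fixed-kernel Metropolis chain.  A scalar or per-component
  δ can be supplied instead.
* **Initialization.**  Nonnegative least squares on the mean equations
  (e_sum ≈ μ̂ᵀN, clipped into support) starts the chain near the posterior
  mass; the fallback puts every component at the count matching the total
  signal.  The sampler is insensitive to this beyond burn-in length.
* **Counts are continuous.**  The posterior treats N_i as real; the KDE
  downstream assumes continuous samples.  Only the synthetic aggregate
  generator rounds to whole cells.
* **Defaults.**  burn-in 5000 sweeps, 10000 retained samples, thin 1,
  M = 10⁶ — sized so a 10-line problem runs in seconds; the reference study
  never states its chain lengths, so these are engineering choices.

Each component's marginal posterior density is estimated from the retained
samples by a Gaussian-kernel KDE with the Gaussian-reference plug-in
bandwidth h = 1.06 s k^(−1/5) (`cellmix.density`).  The density is
evaluated on 2048 equally spaced points spanning [max(0, min − 3h),
max + 3h]; no boundary correction is applied at zero, so a density leaning
on the boundary can lose a few percent of its mass (the integral invariant
tolerates down to 0.95).  The reported point estimate N̂_i is the marginal
MAP — the grid arg-max, ties resolved toward the smaller value.  The
marginal (not joint) mode is a modeling choice: per-component posteriors
are what the method visualizes and summarizes, and the reported N̂ vector is
read component-wise.  Interval summaries are provided as raw chain
quantiles and are labelled as a convenience, not a density-based credible
interval.

The composition ratio is π̂ = N̂ / Σ N̂_i, and accuracy against a known truth
is the root square error e = ‖π − π̂‖₂ (`cellmix.composition`).  Unlike an
RMSE this does not shrink mechanically as n grows, because ratios sum to 1.
Ratios are rounded to 3 decimals only in printed reports, never internally.

## Synthetic data

`cellmix.simulate` reproduces the validation design: n = m, mean matrix
cyclic (row i is the first row rotated left by i positions — the direction
is fixed only for reproducibility, either one is the same design up to
relabeling), per-cell attributes Gaussian with constant coefficient of
variation (σ_ij = cv·μ_ij), p = 2000 profiling cells per line by default,
and the aggregate built by literally summing per-cell draws for the true
count vector.  Draws are used untruncated: at cv = 1 a Gaussian attribute
is frequently negative, but the estimator consumes only means and
variances.  Profiling and aggregate draws come from separate RNG streams
spawned from the master seed so tests can vary one while holding the other.

Two stress knobs:

* **Similarity k ∈ [0, 1):** the first row runs linearly from 1000k to
  1000; k → 1 collapses the lines onto one profile and the deconvolution
  becomes ill-posed (k = 1 is rejected).  Default sweep grid
  {0.1, 0.2, …, 0.8}.
* **Coefficient of variation:** larger cv inflates the aggregate variance
  and widens the posterior.  Default sweep grid {1, 2, 3, 4, 5}.

What the generator emulates: additive aggregation, line-specific Gaussian
attribute distributions, profile estimation noise at finite p.  What it
does not emulate: profile drift between phases, cell–cell interactions,
measurement background, non-Gaussian single-cell distributions, or partial
imaging of a well.  Passing tests therefore demonstrate correctness of the
inference machinery under the model's own assumptions, not robustness of
the assay.

## Resolution limits of the reference design

The 10×10 cyclic design with first row [100 … 1000] at cv = 1 is
deliberately hard: every line contributes to every attribute and the
circulant mean matrix is strongly collinear.  The inverse Fisher
information of the aggregate likelihood at N = [500 … 500] puts the
marginal posterior SD near 60 cells per component (a unit test computes
this in closed form), and profile noise at p = 2000 adds a comparable
amount.  A single aggregate draw therefore cannot determine each component
much better than several tens of cells, whatever the sampler does; the
stochastic-recovery acceptance tests assert tighter published tolerances
and are expected to fail for the dense scenarios — the failures measure the
design's intrinsic noise, not a sampler defect.  The single-line scenario
(one line present, nine absent) is much better determined and is recovered
robustly, with a characteristic few-percent downward shift of the present
component because the nine floor-bounded absent components absorb a little
signal.

## Problem sizes used in the test suite

The unit and acceptance tests run the 10×10 design at p = 2000 with
burn-in 2000 / 5000 retained samples, the 1-D oracle toys with 20000
retained samples, and the sweep trend checks with k ∈ {0.1, 0.45, 0.8} and
cv ∈ {1, 5} at 3 replicates with burn-in 1000 / 2000 samples.  These sizes
were chosen so the full suite runs in well under a minute per heavy test
while leaving the asserted tolerances unchanged.

## Known limitations

* The CLT likelihood degrades for lines with very few cells; the positivity
  floor keeps the math defined there but nothing corrects the
  approximation.
* Profile drift between profiling and mixture measurement is not modeled
  and produces confidently wrong counts for every line whose attributes
  shifted (the blue-channel behaviour of SW480-style setups); detecting or
  correcting drift is out of scope.
* No convergence diagnostics beyond per-component acceptance rates are
  computed (no R̂, no effective sample size).
* Attribute independence is assumed, not checked.
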