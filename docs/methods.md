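# Methods

## Selection model

A biallelic locus with alleles A and a evolves at constant effective
population size under constant selection. Relative fitnesses are
w_A = 1+s, w_a = 1 for haploids and w_AA = 1+s, w_Aa = 1+hs, w_aa = 1
for diploids, with genotype frequencies at Hardy–Weinberg proportions
every generation (no inbreeding parameter). The deterministic
one-generation map is

    p' = w_A p / (w_A p + w_a (1-p))                         (haploid)
    p' = (w_AA p² + w_Aa p(1-p)) / mean fitness              (diploid)

with 0 and 1 absorbing. For codominance (h = ½) the continuous-time
approximation has the closed form p_t = expit(logit(p_0) + r t), with
r = s for haploids and r = s/2 for diploids: logit-transformed
frequencies are exactly linear in time. No closed form exists for
general h, so the recessive/dominant cases are handled numerically via
the discrete map. The two models agree to <10⁻³ over 60 generations for
s ≤ 0.01 and diverge visibly at s ≥ 0.1 — the origin of the bias
correction below.

Both `s` and `h` are assumed constant in time and shared across
replicates; replicates start from the same allele frequency. Linked
loci, clonal interference, mutation, migration, and time-varying
N_e are outside the model.

## Wright–Fisher simulator and Pool-Seq noise

Population dynamics: each generation the expected post-selection
frequency is resampled binomially over the gamete pool (N_e copies for
haploids, 2·N_e for diploids). Observation noise mimics Pool-Seq: per
sample the coverage is drawn Poisson(λ) and the allele count
binomially at the population frequency; an optional finite sequencing
pool adds an intermediate binomial stage (off by default, matching the
two-step Poisson→binomial recipe). A coverage draw of zero is a
missing observation, not an error.

The default design — 6 replicates, N_e = 300 diploid, 60 generations
sampled every 10, λ = 80 — is the standard E&R scenario of recent
*Drosophila*-scale experiments and is the base condition of every
evaluation here. Datasets are generated in fixed-size locus blocks,
each with an RNG stream spawned deterministically from the root seed,
so enlarging a dataset never reshuffles earlier loci.

What the generator does **not** emulate: linkage and hitchhiking,
overlapping generations, variable coverage along the genome, mapping
or allele-calling artifacts, and uncertainty in N_e (the true value is
handed to the neutrality test). Passing tests therefore demonstrate
correct behaviour of the estimators under the model's own assumptions,
not robustness to their violation in real data.

## Estimation pipeline

1. **Consensus.** Replicate frequencies are averaged per time point,
   unweighted. A replicate stops contributing from the first time its
   *observed* frequency is zero (inclusive): conditioning on retention
   would otherwise bias the fit upward. Missing observations are
   skipped without masking. Time points with no contributing replicate
   are dropped; fewer than two surviving points means no estimate.
2. **LLS.** OLS of logit(consensus) on generations over the points
   strictly inside (0,1); slope → s (haploid) or 2·slope (diploid),
   intercept → p₀. Observed frequencies of exactly 1 carry no logit
   information and are dropped from the fit, mirroring the
   loss-masking logic symmetrically at the upper boundary. Optional
   weights proportional to the summed coverage of contributing
   replicates are available behind a flag; the default is unweighted,
   since coverage has little effect on accuracy above ~40×.
3. **Discrete-model bias correction.** LLS fits the continuous-time
   model, which under strong selection underestimates s for discrete
   generations. The correction iterates the additive update
   s ← s + (ŝ − LLS(det-trajectory(p̂₀, s))) to its fixed point, i.e.
   solves for the s whose deterministic discrete trajectory re-estimates
   to the observed ŝ. A single iteration is the plain "add the
   deterministic discrepancy" recipe; iterating removes the residual
   second-order bias (at s = 0.3 the one-pass correction leaves ~0.013,
   the fixed point ~5·10⁻⁴). The correction is applied unconditionally:
   it vanishes smoothly as ŝ → 0, which removes the need for a
   "large ŝ" trigger threshold. Tolerance 10⁻⁶, at most 30 iterations,
   s floored at −0.99 to keep fitnesses positive; if the deterministic
   trajectory is monomorphic at almost all sampled times the correction
   is skipped and flagged.
4. **Survival-conditioning correction** (rare alleles). Loss-masking
   conditions on allele retention, which inflates the consensus of rare
   alleles even under neutrality. When the starting frequency is low
   relative to N_e — expected copy number below 30, or exact neutral
   loss probability by the final sampled generation above 1%, computed
   from the Wright–Fisher transition matrix and cached per design —
   1,000 locus-specific neutral simulations under the same design are
   run through the identical masking consensus, and their mean excess
   over p₀ is subtracted per time point (clipped to [0,1]). This
   removes most, not all, of the conditioning bias (the residual stems
   from clipping and from seeding the null at the noisy observed p₀);
   the associated test asserts the qualitative bias removal.
5. **NLS.** For loci that depart from codominance, (s, h) are
   co-estimated by nonlinear least squares of observed consensus
   frequencies against the discrete deterministic trajectory
   (frequency-scale residuals — the logit scale would be undefined at
   boundary points). p₀ is fixed at the first consensus value, since
   three free parameters on ≤7 points are poorly identified. Bounds
   s ∈ [−0.5, 1.5], h ∈ [−1, 2]; start at (LLS ŝ, 0.5) with one random
   restart on failure — multiple local optima are rare, so a single
   restart suffices. Haploids have no dominance; only s is fitted.
6. **Automatic switching.** A quadratic term added to the logit-linear
   model detects the curvature that non-codominance produces. The
   partial F-test of the t² coefficient (equivalent to its two-sided
   t-test; guarded for numerically perfect fits, needing ≥4 interior
   points) yields a p-value; below the threshold (default 0.1) NLS is
   used, otherwise bias-corrected LLS. NLS non-convergence falls back
   to LLS with a flag. The threshold trades the bias of wrongly
   assuming h = ½ against the larger variance of NLS; 0.1 is a good
   compromise, with specificity best at low starting frequencies.

## Neutrality test

A parametric bootstrap: for each locus, neutral (s = 0) datasets are
simulated from the observed starting consensus frequency with the same
replicate count, sampling grid, N_e and the *observed coverages
reused*, and pushed through the identical estimator. The p-value is
(1 + #{s* ≥ ŝ}) / (1 + n_sims) — one-sided for positive selection, with
an add-one pseudo-count so p is never zero (the plain fraction and a
two-sided variant are available via flags). Null simulations that
yield no estimate count as not exceeding; loci whose own consensus
starts at 0/1 or yields no estimate get no p-value and are excluded
from power denominators. Default n_sims = 1000; fewer than 100 draws a
granularity warning. Matching the null to the observed coverage makes
the test calibrated — null-simulated data yield uniform p-values —
which is verified by a KS test in the suite. A consequence worth
stating plainly: with a single replicate at N_e = 300, the matched null
carries the full drift variance, so no calibrated test can detect
s ≲ 0.1 at α = 0.01 regardless of coverage; power claims that exceed
this ceiling imply a null that ignores part of the noise.

Two-time-point tests (Pearson chi-squared without continuity
correction; Cochran–Mantel–Haenszel across replicate strata with the
conventional 0.5 continuity term, removable) are provided for
compatibility with standard E&R scans, along with Benjamini–Hochberg
FDR adjustment and a positional filter that keeps only outliers
supported by another outlier within 1 kb on the same chromosome.

## Accuracy evaluation

Estimator quality is summarised by the relative root-mean-squared
error rRMSE = RMSE(ŝ, s) / mean(s) over a bin of loci, which captures
bias and variance on a scale relative to the mean true coefficient; it
is undefined where the mean true s is zero. The accuracy map bins loci
on an equal-width (p₀, s) grid over [0,1] × [0,0.3] — 10×10 by default
at ≤10⁵ loci so each bin keeps ~10³ loci; percentile-bootstrap
confidence intervals (200 resamples) are available per bin. For
comparisons with bounded-prior methods, estimates can be projected to
[−0.2, 1.0]. Loci without an estimate are excluded from rRMSE — note
this conditions on estimability and flatters the hardest corners of
the parameter space (p₀ > 0.95), where half the loci return nothing.

Experiment runners reproduce the main simulation studies at desk
scale: power surfaces over (s, p₀); the equal-sequencing-effort
comparison (6 replicates × 80× versus 1 × 480×, where replication wins
across the whole s range because it averages out drift, not just
sequencing noise); and one-parameter design sweeps around the standard
design (measurement interval, coverage, duration, N_e, replicates),
reported as percent change in rRMSE. In those sweeps N_e and replicate
number dominate; halving the experiment's duration from 60 to 30
generations hurts markedly, while interval and coverage matter little.

## Numerical choices and degenerate inputs

* Logit computed as log(p) − log1p(−p); interior-point masks use an
  absolute guard of 10⁻¹² against float-rounded boundaries.
* Row-wise closed-form weighted OLS powers all batch fits; a row is
  invalid with fewer than two weighted points or a degenerate time
  spread.
* Constant trajectories give s = 0 with h flagged unidentifiable
  (|ŝ| < 10⁻⁸).
* The quadratic test returns p = 1 when the quadratic term improves an
  already-perfect linear fit by less than 10⁻¹² of the total sum of
  squares, and p = 0 for an exactly quadratic fit with curvature.
* The neutral loss-probability trigger uses the exact transition
  matrix up to 4,000 gametes; above that, loss of an allele with ≥30
  expected copies is negligible on these time horizons.
* All stochastic components draw from explicitly passed
  `numpy.random.Generator` streams; dataset generation is
  block-seeded, so results are bit-reproducible for a given seed and
  stable under dataset growth.

## Problem sizes in the shipped evaluation

Power conditions run 1,000–2,000 loci with 1,000 null simulations per
locus; the accuracy map uses 10⁵ loci; NLS calibration uses 2,000 loci
per dominance value; the bootstrap-calibration check uses 400 null
loci at 400 simulations each. These sizes put Monte-Carlo error well
inside the asserted margins while keeping the full evaluation in the
minutes range on one CPU.

## Known limitations

* The logit scale does not fully stabilise variance: by the delta
  method var(logit p̂) ≈ var(p̂)/(p(1−p))², so the drift+sampling
  variance of logit frequencies still varies severalfold across
  starting frequencies. Unweighted OLS is nevertheless adequate, as
  the accuracy evaluation shows; the coverage-weight option addresses
  the sampling-noise part only.
* The survival-conditioning correction is approximate (mean-excess
  subtraction on the frequency scale) and removes ~¾ of the
  conditioning bias in the tested conditions.
* p-values assume the supplied N_e is correct; over-stated N_e makes
  the test anti-conservative.
* Estimates for loci starting above ~0.95 or with s below ~0.01 are
  intrinsically poor (short or drift-dominated trajectories); rRMSE
  there exceeds 0.9 and no design tweak within the studied ranges
  fixes it.
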