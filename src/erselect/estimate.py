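"""Estimation of selection parameters from replicated trajectories.

The estimators operate on a consensus trajectory: per time point the
unweighted mean of observed frequencies over the replicates in which the
allele has not yet been lost (a replicate is excluded from the first
time its observed frequency hits zero onwards, since conditioning on
retention would otherwise bias the fit).

* LLS — ordinary least squares of logit-transformed consensus
  frequencies on generations; the slope encodes ``s`` (times two for
  diploids) and the intercept ``logit(p0)``.  Assumes codominance.
* discrete-model bias correction — LLS fits the continuous-time model;
  under strong selection populations evolving in discrete generations
  deviate from it.  The correction finds the ``s`` whose deterministic
  discrete trajectory re-estimates to the observed LLS value (fixed
  point of adding the deterministic re-estimation discrepancy).
* survival-conditioning correction — for rare alleles the loss-masking
  consensus conditions on retention; locus-specific neutral simulations
  quantify the resulting excess, which is subtracted.
* NLS — nonlinear least squares of observed frequencies against the
  discrete deterministic trajectory, co-estimating ``s`` and ``h``.
* automatic switching — a quadratic term added to the logit-linear
  model detects curvature caused by non-codominance; if its p-value
  falls below a threshold (default 0.1) NLS replaces LLS.

Batch variants (``*_batch``) vectorise over loci and are the engine of
the parametric bootstrap and the evaluation experiments.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Tuple

import numpy as np
from scipy import optimize, stats
from scipy.special import expit

from .model import FreqSeries, Ploidy, _check_ploidy, _det_traj_batch
from .simulate import SimDesign, Trajectory, sample_poolseq, simulate_trajectories

__all__ = [
    "EstimationError",
    "EstimateResult",
    "Trajectory",
    "combine_replicates",
    "lls_estimate",
    "bias_correct",
    "condition_on_survival_correct",
    "nls_estimate",
    "quadratic_term_test",
    "estimate_auto",
    "consensus_batch",
    "lls_pipeline_batch",
    "bias_correct_batch",
    "neutral_loss_probability",
]

_EPS = 1e-12


class EstimationError(ValueError):
    """Raised when a trajectory carries too little information to fit."""


@dataclass
class EstimateResult:
    """Fitted selection parameters for one locus."""

    s_hat: float
    p0_hat: float
    h_hat: float
    method: str  # "LLS" or "NLS"
    quad_pvalue: Optional[float] = None
    converged: bool = True
    n_points_used: int = 0
    notes: Tuple[str, ...] = ()

    def with_(self, **kw) -> "EstimateResult":
        d = self.__dict__.copy()
        d.update(kw)
        return EstimateResult(**d)


# ---------------------------------------------------------------------------
# consensus construction
# ---------------------------------------------------------------------------


def consensus_batch(freqs: np.ndarray, cov: Optional[np.ndarray] = None):
    """Loss-masked replicate consensus for a batch of loci.

    ``freqs`` has shape ``(n, R, T)`` with NaN marking missing
    observations.  A replicate stops contributing from the first time
    point at which its observed frequency is zero (inclusive).

    Returns ``(consensus, contrib, covsum)`` of shape ``(n, T)``:
    per-time mean over contributing replicates (NaN when none), the
    number of contributing replicates, and their summed coverage
    (zeros when ``cov`` is None).
    """
    freqs = np.asarray(freqs, dtype=float)
    if freqs.ndim == 2:
        freqs = freqs[None]
    obs = np.isfinite(freqs)
    lost = obs & (freqs <= 0.0)
    unusable = np.logical_or.accumulate(lost, axis=2)
    use = obs & ~unusable
    contrib = use.sum(axis=1)
    total = np.where(use, freqs, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cons = np.where(contrib > 0, total / np.maximum(contrib, 1), np.nan)
    if cov is not None:
        cov = np.asarray(cov)
        if cov.ndim == 2:
            cov = cov[None]
        covsum = np.where(use, cov, 0).sum(axis=1)
    else:
        covsum = np.zeros_like(contrib)
    return cons, contrib, covsum


def combine_replicates(traj: Trajectory, return_diagnostics: bool = False):
    """Consensus frequency series of one locus (loss-masked mean).

    Time points with no contributing replicate are dropped.  Raises
    :class:`EstimationError` when fewer than two usable time points
    survive.
    """
    cons, contrib, covsum = consensus_batch(traj.freqs[None], None if traj.cov is None else traj.cov[None])
    cons, contrib, covsum = cons[0], contrib[0], covsum[0]
    keep = contrib > 0
    if keep.sum() < 2:
        raise EstimationError("fewer than two usable time points in consensus")
    fs = FreqSeries(traj.times[keep], cons[keep])
    if return_diagnostics:
        return fs, contrib[keep], covsum[keep]
    return fs


# ---------------------------------------------------------------------------
# logit-linear least squares
# ---------------------------------------------------------------------------


def _masked_wls(t: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Row-wise weighted OLS of y on t; weight 0 excludes a point.

    Returns ``(slope, intercept, n_points)``; rows with fewer than two
    weighted points (or a degenerate time spread) yield NaN.
    """
    t = np.asarray(t, dtype=float)
    y0 = np.where(w > 0, y, 0.0)
    npts = (w > 0).sum(axis=1)
    W = w.sum(axis=1)
    sx = (w * t).sum(axis=1)
    sy = (w * y0).sum(axis=1)
    sxx = (w * t * t).sum(axis=1)
    sxy = (w * t * y0).sum(axis=1)
    denom = W * sxx - sx * sx
    ok = (npts >= 2) & (denom > _EPS * np.maximum(W * sxx, 1.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = np.where(ok, (W * sxy - sx * sy) / denom, np.nan)
        intercept = np.where(ok, (sy - slope * sx) / np.maximum(W, _EPS), np.nan)
    return slope, intercept, npts


def _slope_factor(ploidy: str) -> float:
    # Eqs. of the codominant logit-linear model: slope = s (haploid), s/2 (diploid)
    return 1.0 if ploidy == "haploid" else 2.0


def lls_batch(cons: np.ndarray, times: np.ndarray, ploidy: Ploidy, covsum=None, weights=None):
    """LLS on consensus rows; returns ``(s_hat, p0_hat, n_points)``.

    Only frequencies strictly inside (0, 1) enter the fit (boundary
    points carry no logit information).  ``weights="coverage"`` uses the
    per-point summed coverage of contributing replicates.
    """
    _check_ploidy(ploidy)
    interior = np.isfinite(cons) & (cons > 0.0) & (cons < 1.0)
    y = np.where(interior, cons, 0.5)
    y = np.log(y) - np.log1p(-y)
    if weights == "coverage":
        if covsum is None:
            raise ValueError("coverage weights requested but no coverages available")
        w = np.where(interior, np.asarray(covsum, dtype=float), 0.0)
    elif weights in (None, "none"):
        w = interior.astype(float)
    else:
        raise ValueError(f"unknown weights scheme {weights!r}")
    slope, intercept, npts = _masked_wls(times, y, w)
    s_hat = _slope_factor(ploidy) * slope
    p0_hat = expit(intercept)
    p0_hat = np.where(np.isfinite(intercept), p0_hat, np.nan)
    return s_hat, p0_hat, npts


def lls_estimate(consensus: FreqSeries, ploidy: Ploidy, weights=None, covsum=None) -> EstimateResult:
    """Fit the logit-linear model to a consensus series.

    ``s_hat`` comes from the slope, ``p0_hat`` from the intercept;
    ``h`` is 0.5 by assumption.  Needs at least two interior points.
    """
    cons = consensus.freqs[None]
    s, p0, npts = lls_batch(
        cons, consensus.generations, ploidy,
        covsum=None if covsum is None else np.asarray(covsum)[None],
        weights=weights,
    )
    if not np.isfinite(s[0]):
        raise EstimationError("LLS needs >= 2 time points strictly inside (0, 1)")
    return EstimateResult(
        s_hat=float(s[0]), p0_hat=float(p0[0]), h_hat=0.5,
        method="LLS", n_points_used=int(npts[0]),
    )


# ---------------------------------------------------------------------------
# discrete-model bias correction
# ---------------------------------------------------------------------------


def bias_correct_batch(
    s_hat: np.ndarray,
    p0_hat: np.ndarray,
    times: np.ndarray,
    ploidy: Ploidy,
    h: float = 0.5,
    tol: float = 1e-6,
    max_iter: int = 30,
):
    """Discrete-model correction of LLS estimates, vectorised over loci.

    Solves for the ``s`` whose deterministic discrete trajectory
    (started at ``p0_hat``, evaluated at the sampling times) re-estimates
    under LLS to the observed ``s_hat``, by iterating the additive
    update ``s <- s + (s_hat - s_re)``.  The first iteration is the
    plain one-pass correction; further iterations remove the residual
    bias that remains under strong selection.

    Returns ``(s_corrected, skipped)``; ``skipped`` flags loci whose
    deterministic trajectory was monomorphic at (almost) all sampled
    times, for which the correction is not applied.
    """
    s_hat = np.atleast_1d(np.asarray(s_hat, dtype=float))
    p0_hat = np.atleast_1d(np.asarray(p0_hat, dtype=float))
    times = np.asarray(times, dtype=int)
    factor = _slope_factor(ploidy)
    s_c = s_hat.copy()
    skipped = np.zeros(s_hat.shape, dtype=bool)
    idx = np.flatnonzero(
        np.isfinite(s_hat) & np.isfinite(p0_hat) & (p0_hat > 0.0) & (p0_hat < 1.0)
    )
    skipped[np.isfinite(s_hat) & ~np.isin(np.arange(s_hat.size), idx)] = True
    for _ in range(max_iter):
        if idx.size == 0:
            break
        traj = _det_traj_batch(p0_hat[idx], s_c[idx], h, ploidy, times)
        interior = (traj > _EPS) & (traj < 1.0 - _EPS)
        y = np.where(interior, traj, 0.5)
        y = np.log(y) - np.log1p(-y)
        slope, _, _ = _masked_wls(times, y, interior.astype(float))
        s_re = factor * slope
        bad = ~np.isfinite(s_re)
        if bad.any():
            s_c[idx[bad]] = s_hat[idx[bad]]
            skipped[idx[bad]] = True
        good = ~bad
        sel = idx[good]
        delta = s_hat[sel] - s_re[good]
        s_c[sel] = np.maximum(s_c[sel] + delta, -0.99)  # fitness must stay positive
        idx = sel[np.abs(delta) >= tol]
    return s_c, skipped


def bias_correct(est: EstimateResult, sampling_times, ploidy: Ploidy) -> EstimateResult:
    """Apply the discrete-model correction to an LLS result."""
    if not (np.isfinite(est.s_hat) and np.isfinite(est.p0_hat)):
        raise EstimationError("bias correction needs finite s_hat and p0_hat")
    s_c, skipped = bias_correct_batch(
        np.array([est.s_hat]), np.array([est.p0_hat]), sampling_times, ploidy
    )
    notes = est.notes + (("bias_correction_skipped",) if skipped[0] else ("bias_corrected",))
    return est.with_(s_hat=float(s_c[0]), notes=notes)


# ---------------------------------------------------------------------------
# survival-conditioning correction
# ---------------------------------------------------------------------------


@lru_cache(maxsize=32)
def _loss_prob_curve(n_gametes: int, t: int) -> np.ndarray:
    """P(neutral allele lost by generation t | starting copy number i)
    for i = 0..n_gametes, from the exact Wright-Fisher transition matrix."""
    states = np.arange(n_gametes + 1)
    # q_t(i) = sum_j P(j | i) q_{t-1}(j); start from the indicator of state 0
    trans = stats.binom.pmf(states[None, :], n_gametes, states[:, None] / n_gametes)
    q = np.zeros(n_gametes + 1)
    q[0] = 1.0
    for _ in range(t):
        q = trans @ q
    return q


def neutral_loss_probability(p0: float, n_gametes: int, t: int) -> float:
    """Probability a neutral allele at frequency ``p0`` is lost within
    ``t`` Wright-Fisher generations (gamete pool of ``n_gametes``).

    Exact for moderate pool sizes; for pools above 4,000 gametes loss of
    an allele with >= 30 expected copies is negligible within the time
    horizons considered and 0 is returned (alleles below that threshold
    are handled by the copy-number trigger before this is consulted).
    """
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("p0 must lie in [0, 1]")
    if p0 == 0.0:
        return 1.0
    if n_gametes > 4000:
        return 0.0
    q = _loss_prob_curve(int(n_gametes), int(t))
    i = int(round(p0 * n_gametes))
    return float(q[min(max(i, 0), n_gametes)])


def _survival_trigger(p0: float, ne: int, ploidy: str, t_final: int) -> bool:
    n_gam = ne if ploidy == "haploid" else 2 * ne
    if p0 * n_gam < 30:
        return True
    return neutral_loss_probability(p0, n_gam, t_final) > 0.01


def condition_on_survival_correct(
    traj: Trajectory,
    ne: Optional[int],
    design: SimDesign,
    rng: np.random.Generator,
    n_sims: int = 1000,
) -> FreqSeries:
    """Correct a consensus trajectory for conditioning on allele survival.

    Loss-masking keeps only replicates in which the allele survived;
    for rare alleles the surviving subset drifts upwards even without
    selection.  Locus-specific neutral simulations under the same design
    (same starting frequency, replicate count, sampling grid and
    coverage model, with the same loss-masking consensus) quantify that
    excess, whose per-time-point mean is subtracted from the observed
    consensus.  ``ne=None`` (or infinite) declares a drift-free input
    and leaves the consensus unchanged.
    """
    fs = combine_replicates(traj)
    p0_obs = float(fs.freqs[0])
    if p0_obs <= 0.0:
        raise EstimationError("observed starting frequency is 0; nothing to correct")
    if ne is None or not np.isfinite(ne):
        return fs
    R = traj.n_replicates
    null = simulate_trajectories(
        np.full(n_sims, p0_obs), 0.0, 0.5,
        ne=int(ne), ploidy=design.ploidy,
        sampling_times=fs.generations, replicates=R, rng=rng,
    )
    alt, cov = sample_poolseq(null, design.mean_coverage, rng, pool_size=design.pool_size)
    with np.errstate(invalid="ignore", divide="ignore"):
        f_null = np.where(cov > 0, alt / np.maximum(cov, 1), np.nan)
    cons_null, _, _ = consensus_batch(f_null)
    excess = np.nanmean(cons_null, axis=0) - p0_obs
    excess = np.where(np.isfinite(excess), excess, 0.0)
    corrected = np.clip(fs.freqs - excess, 0.0, 1.0)
    return FreqSeries(fs.generations, corrected)


# ---------------------------------------------------------------------------
# nonlinear least squares (s and h jointly)
# ---------------------------------------------------------------------------

_NLS_BOUNDS_S = (-0.5, 1.5)
_NLS_BOUNDS_H = (-1.0, 2.0)


def _det_traj_scalar(p0: float, s: float, h: float, ploidy: str, times) -> np.ndarray:
    """Deterministic discrete trajectory at the given times (plain-float
    loop; fast enough inside the NLS residual)."""
    out = np.empty(len(times))
    wanted = {int(t): k for k, t in enumerate(times)}
    p = float(p0)
    if 0 in wanted:
        out[wanted[0]] = p
    t_max = max(int(t) for t in times)
    if ploidy == "haploid":
        for t in range(1, t_max + 1):
            num = (1.0 + s) * p
            p = num / (num + 1.0 - p)
            if t in wanted:
                out[wanted[t]] = p
    else:
        w_aa = 1.0 + s
        w_het = 1.0 + h * s
        for t in range(1, t_max + 1):
            q = 1.0 - p
            hom = w_aa * p * p
            het = w_het * p * q
            p = (hom + het) / (hom + 2.0 * het + q * q)
            if t in wanted:
                out[wanted[t]] = p
    return out


def nls_estimate(
    consensus: FreqSeries,
    ploidy: Ploidy,
    start: Optional[Tuple[float, float]] = None,
    rng: Optional[np.random.Generator] = None,
) -> EstimateResult:
    """Co-estimate ``s`` and ``h`` by nonlinear least squares.

    The starting frequency is fixed at the first consensus value and the
    discrete deterministic trajectory is fitted to the observed
    frequencies (frequency-scale residuals).  The optimiser starts from
    the LLS estimate with ``h = 0.5`` and performs one random restart on
    failure.  Haploids have no dominance; only ``s`` is fitted and
    ``h_hat`` is NaN.
    """
    _check_ploidy(ploidy)
    times = consensus.generations
    freqs = consensus.freqs
    interior = (freqs > 0.0) & (freqs < 1.0)
    if interior.sum() < 3:
        raise EstimationError("NLS needs >= 3 time points strictly inside (0, 1)")
    p0 = float(freqs[0])
    if not 0.0 < p0 < 1.0:
        raise EstimationError("NLS needs an interior starting frequency")
    t_rel = (times - times[0]).tolist()
    obs = freqs

    if start is None:
        try:
            s0 = lls_estimate(consensus, ploidy).s_hat
        except EstimationError:
            s0 = 0.1
        start = (float(np.clip(s0, *_NLS_BOUNDS_S)), 0.5)

    if ploidy == "haploid":
        def resid(theta):
            return _det_traj_scalar(p0, theta[0], 0.5, "haploid", t_rel) - obs
        x0 = np.array([start[0]])
        lo, hi = np.array([_NLS_BOUNDS_S[0]]), np.array([_NLS_BOUNDS_S[1]])
    else:
        def resid(theta):
            return _det_traj_scalar(p0, theta[0], theta[1], "diploid", t_rel) - obs
        x0 = np.array([start[0], np.clip(start[1], *_NLS_BOUNDS_H)])
        lo = np.array([_NLS_BOUNDS_S[0], _NLS_BOUNDS_H[0]])
        hi = np.array([_NLS_BOUNDS_S[1], _NLS_BOUNDS_H[1]])

    def _fit(x_init):
        return optimize.least_squares(resid, x_init, bounds=(lo, hi), xtol=1e-10, ftol=1e-12)

    res = _fit(x0)
    notes: Tuple[str, ...] = ()
    if not res.success:
        if rng is None:
            rng = np.random.default_rng(0)
        res2 = _fit(rng.uniform(lo, hi))
        if res2.success or res2.cost < res.cost:
            res = res2
        notes = ("nls_restarted",)

    s_hat = float(res.x[0])
    h_hat = float(res.x[1]) if ploidy == "diploid" else float("nan")
    if abs(s_hat) < 1e-8:
        h_hat = float("nan")
        notes = notes + ("h_unidentifiable",)
    return EstimateResult(
        s_hat=s_hat, p0_hat=p0, h_hat=h_hat, method="NLS",
        converged=bool(res.success), n_points_used=int(len(t_rel)),
        notes=notes,
    )


# ---------------------------------------------------------------------------
# codominance diagnostic and automatic switching
# ---------------------------------------------------------------------------


def quadratic_term_test(consensus: FreqSeries) -> Optional[float]:
    """Two-sided p-value of a quadratic term added to the logit-linear
    model (curvature indicates departure from codominance).

    Needs at least four interior time points; returns None otherwise.
    Implemented as the partial F-test of the t^2 term (equivalent to the
    two-sided t-test of its coefficient), with guards for numerically
    perfect fits.
    """
    times = consensus.generations.astype(float)
    freqs = consensus.freqs
    interior = (freqs > 0.0) & (freqs < 1.0)
    t = times[interior]
    if t.size < 4:
        return None
    y = np.log(freqs[interior]) - np.log1p(-freqs[interior])
    tc = t - t.mean()  # centring keeps the Vandermonde well conditioned
    rss_lin = float(np.sum((np.polyval(np.polyfit(tc, y, 1), tc) - y) ** 2))
    rss_quad = float(np.sum((np.polyval(np.polyfit(tc, y, 2), tc) - y) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    tiny = 1e-12 * max(tss, 1e-30)
    improvement = rss_lin - rss_quad
    if improvement <= tiny:
        return 1.0
    if rss_quad <= tiny:
        return 0.0
    df_resid = t.size - 3
    f = improvement / (rss_quad / df_resid)
    return float(stats.f.sf(f, 1, df_resid))


def estimate_auto(
    traj: Trajectory,
    ploidy: Ploidy,
    p_threshold: float = 0.1,
    ne: Optional[int] = None,
    design: Optional[SimDesign] = None,
    rng: Optional[np.random.Generator] = None,
    survival_correction: str = "auto",
    bias_correction: bool = True,
    weights=None,
    n_null: int = 1000,
) -> EstimateResult:
    """Full single-locus pipeline with automatic LLS/NLS switching.

    Consensus construction, optional survival-conditioning correction
    (when ``ne`` is supplied and the starting frequency is low relative
    to it), then the quadratic curvature test: p-values below
    ``p_threshold`` route the locus to NLS, otherwise to bias-corrected
    LLS.  NLS non-convergence falls back to LLS with a note.
    """
    fs, contrib, covsum = combine_replicates(traj, return_diagnostics=True)
    notes: Tuple[str, ...] = ()
    if survival_correction != "off" and ne is not None and np.isfinite(ne):
        p0_obs = float(fs.freqs[0])
        forced = survival_correction == "on"
        if p0_obs > 0 and (
            forced or _survival_trigger(p0_obs, int(ne), ploidy, int(fs.generations[-1]))
        ):
            if design is None:
                raise ValueError("survival correction needs the sampling design")
            if rng is None:
                rng = np.random.default_rng(0)
            fs = condition_on_survival_correct(traj, ne, design, rng, n_sims=n_null)
            notes = notes + ("survival_corrected",)

    pq = quadratic_term_test(fs)
    if pq is not None and pq < p_threshold:
        try:
            est = nls_estimate(fs, ploidy, rng=rng)
            if est.converged:
                return est.with_(quad_pvalue=pq, notes=est.notes + notes)
            notes = notes + ("nls_fallback",)
        except EstimationError:
            notes = notes + ("nls_fallback",)
    est = lls_estimate(fs, ploidy, weights=weights, covsum=covsum if weights == "coverage" else None)
    if bias_correction:
        est = bias_correct(est, fs.generations, ploidy)
    return est.with_(quad_pvalue=pq, notes=est.notes + notes)


# ---------------------------------------------------------------------------
# vectorised pipeline over many loci (bootstrap / evaluation engine)
# ---------------------------------------------------------------------------


def lls_pipeline_batch(
    alt: np.ndarray,
    cov: np.ndarray,
    times: np.ndarray,
    ploidy: Ploidy,
    bias_correction: bool = True,
    weights=None,
):
    """Consensus + LLS (+ bias correction) over a batch of loci.

    ``alt``/``cov`` have shape ``(n, R, T)``.  Returns a dict with
    arrays ``s_hat``, ``p0_hat``, ``n_points``, ``p_start`` (first
    available consensus value, used to seed matched null simulations;
    NaN if none) and ``s_raw`` (pre-correction LLS value).
    """
    alt = np.asarray(alt)
    cov = np.asarray(cov)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(cov > 0, alt / np.maximum(cov, 1), np.nan)
    cons, contrib, covsum = consensus_batch(freqs, cov)
    s_raw, p0_hat, npts = lls_batch(cons, times, ploidy, covsum=covsum, weights=weights)
    if bias_correction:
        s_hat, _ = bias_correct_batch(s_raw, p0_hat, times, ploidy)
    else:
        s_hat = s_raw
    has_cons = np.isfinite(cons)
    first = np.argmax(has_cons, axis=1)
    any_cons = has_cons.any(axis=1)
    p_start = np.where(any_cons, cons[np.arange(cons.shape[0]), first], np.nan)
    return {
        "s_hat": s_hat,
        "s_raw": s_raw,
        "p0_hat": p0_hat,
        "n_points": npts,
        "p_start": p_start,
    }
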