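"""Hypothesis tests for selection on allele-frequency time series.

The central test is a parametric bootstrap of the neutral (``s = 0``)
Wright-Fisher model: neutral datasets matched to the observed locus in
starting frequency, replicate count, sampling grid and coverage are
simulated, the same estimator is applied to each, and the p-value is
the fraction of null estimates at least as large as the observed one
(one-sided for positive selection by default, with an add-one
pseudo-count so p is never exactly zero).

Classic two-time-point tests (Pearson chi-squared, Cochran-Mantel-
Haenszel across replicates), Benjamini-Hochberg FDR adjustment and the
positional neighbor-support filter used in genome scans round out the
module.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.contingency_tables import StratifiedTable
from statsmodels.stats.multitest import multipletests

from .estimate import lls_pipeline_batch
from .simulate import SimDesign, Trajectory, sample_poolseq, simulate_trajectories

__all__ = [
    "TestResult",
    "neutrality_test",
    "neutrality_test_batch",
    "chisq_test",
    "cmh_test",
    "bh_adjust",
    "neighbor_support_filter",
]


@dataclass
class TestResult:
    statistic: float
    pvalue: Optional[float]
    n_null_sims: Optional[int] = None
    qvalue: Optional[float] = None


# ---------------------------------------------------------------------------
# parametric-bootstrap neutrality test
# ---------------------------------------------------------------------------


def neutrality_test_batch(
    alt: np.ndarray,
    cov: np.ndarray,
    times: np.ndarray,
    *,
    ne: int,
    ploidy: str,
    n_sims: int = 1000,
    rng: np.random.Generator,
    bias_correction: bool = True,
    weights=None,
    two_sided: bool = False,
    plain_fraction: bool = False,
    max_chunk: int = 400_000,
) -> pd.DataFrame:
    """Neutrality p-values for a batch of loci, fully vectorised.

    For each locus, ``n_sims`` neutral replicate sets are simulated from
    its observed starting consensus frequency, with the observed
    coverages reused, and run through the identical consensus + LLS
    (+ bias correction) pipeline.  Null simulations that yield no
    estimate (e.g. the allele was lost everywhere) are maximally
    unselected and never exceed the observed value; the denominator is
    always ``n_sims``.

    Returns a DataFrame with columns ``s_hat``, ``p0_hat``, ``pvalue``,
    ``n_points``.  Loci without an observed estimate, or whose starting
    consensus is fixed/lost, get NaN p-values.
    """
    alt = np.asarray(alt)
    cov = np.asarray(cov)
    times = np.asarray(times, dtype=int)
    n, R, T = alt.shape
    obs = lls_pipeline_batch(alt, cov, times, ploidy, bias_correction=bias_correction, weights=weights)
    s_obs = obs["s_hat"]
    p_start = obs["p_start"]
    testable = np.isfinite(s_obs) & np.isfinite(p_start) & (p_start > 0.0) & (p_start < 1.0)
    exceed = np.zeros(n, dtype=int)

    idx_testable = np.flatnonzero(testable)
    per_chunk = max(1, max_chunk // max(n_sims, 1))
    for lo in range(0, idx_testable.size, per_chunk):
        idx = idx_testable[lo : lo + per_chunk]
        m = idx.size * n_sims
        p0_null = np.repeat(p_start[idx], n_sims)
        null_freq = simulate_trajectories(
            p0_null, 0.0, 0.5, ne=ne, ploidy=ploidy,
            sampling_times=times, replicates=R, rng=rng,
        )
        cov_null = np.repeat(cov[idx], n_sims, axis=0)
        alt_null = rng.binomial(cov_null, null_freq)
        res = lls_pipeline_batch(
            alt_null, cov_null, times, ploidy,
            bias_correction=bias_correction, weights=weights,
        )
        s_null = res["s_hat"].reshape(idx.size, n_sims)
        if two_sided:
            cmp = np.abs(s_null) >= np.abs(s_obs[idx])[:, None]
        else:
            cmp = s_null >= s_obs[idx][:, None]
        exceed[idx] = np.nansum(np.where(np.isfinite(s_null), cmp, False), axis=1)

    if plain_fraction:
        pval = exceed / n_sims
    else:
        pval = (1.0 + exceed) / (1.0 + n_sims)
    pval = np.where(testable, pval, np.nan)
    return pd.DataFrame(
        {
            "s_hat": s_obs,
            "p0_hat": obs["p0_hat"],
            "pvalue": pval,
            "n_points": obs["n_points"],
        }
    )


def neutrality_test(
    traj: Trajectory,
    observed_s: float,
    ne: int,
    design: SimDesign,
    n_sims: int = 1000,
    rng: Optional[np.random.Generator] = None,
    **kwargs,
) -> TestResult:
    """Parametric-bootstrap neutrality test for a single locus.

    ``observed_s`` must come from the same estimator configuration that
    is applied to the null simulations (bias-corrected consensus LLS by
    default; see ``bias_correction``/``weights`` keyword options).
    """
    if rng is None:
        rng = np.random.default_rng(design.seed)
    bias_correction = kwargs.pop("bias_correction", True)
    weights = kwargs.pop("weights", None)
    two_sided = kwargs.pop("two_sided", False)
    plain_fraction = kwargs.pop("plain_fraction", False)
    if kwargs:
        raise TypeError(f"unexpected keyword arguments {sorted(kwargs)}")
    if traj.alt is None or traj.cov is None:
        cov = np.full(traj.freqs.shape, int(round(design.mean_coverage)))
        alt = np.round(np.nan_to_num(traj.freqs) * cov).astype(int)
    else:
        alt, cov = traj.alt, traj.cov
    times = np.asarray(traj.times, dtype=int)
    obs = lls_pipeline_batch(
        alt[None], cov[None], times, design.ploidy,
        bias_correction=bias_correction, weights=weights,
    )
    p_start = float(obs["p_start"][0])
    if not (np.isfinite(observed_s) and 0.0 < p_start < 1.0):
        return TestResult(statistic=float(observed_s), pvalue=None, n_null_sims=n_sims)
    R = traj.n_replicates
    null_freq = simulate_trajectories(
        np.full(n_sims, p_start), 0.0, 0.5, ne=ne, ploidy=design.ploidy,
        sampling_times=times, replicates=R, rng=rng,
    )
    cov_null = np.repeat(cov[None], n_sims, axis=0)
    alt_null = rng.binomial(cov_null, null_freq)
    res = lls_pipeline_batch(
        alt_null, cov_null, times, design.ploidy,
        bias_correction=bias_correction, weights=weights,
    )
    s_null = res["s_hat"]
    if two_sided:
        cmp = np.abs(s_null) >= abs(observed_s)
    else:
        cmp = s_null >= observed_s
    exceed = int(np.nansum(np.where(np.isfinite(s_null), cmp, False)))
    pval = exceed / n_sims if plain_fraction else (1.0 + exceed) / (1.0 + n_sims)
    return TestResult(statistic=float(observed_s), pvalue=float(pval), n_null_sims=n_sims)


# ---------------------------------------------------------------------------
# classic count-based tests
# ---------------------------------------------------------------------------


def chisq_test(counts_t0: Sequence[int], counts_t1: Sequence[int]) -> TestResult:
    """Pearson chi-squared (1 df, no continuity correction) on the 2x2
    table of allele counts at two time points."""
    table = np.asarray([list(counts_t0), list(counts_t1)], dtype=float)
    if table.shape != (2, 2) or np.any(table < 0):
        raise ValueError("expected two non-negative allele count pairs")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        return TestResult(statistic=float("nan"), pvalue=None)
    stat, pval, _, _ = stats.chi2_contingency(table, correction=False)
    return TestResult(statistic=float(stat), pvalue=float(pval))


def cmh_test(tables: Iterable, correction: bool = True) -> TestResult:
    """Cochran-Mantel-Haenszel test (1 df) across replicate strata.

    ``tables`` is one 2x2 allele-count table per replicate.  The
    conventional 0.5 continuity correction is applied unless
    ``correction=False``.  Strata in which a margin is empty carry no
    information; if all strata are degenerate the p-value is absent.
    """
    arrs = [np.asarray(t, dtype=float) for t in tables]
    if not arrs:
        raise ValueError("need at least one stratum")
    ok = [
        a for a in arrs
        if a.shape == (2, 2) and not (np.any(a.sum(0) == 0) or np.any(a.sum(1) == 0))
    ]
    if not ok:
        return TestResult(statistic=float("nan"), pvalue=None)
    stacked = np.stack(ok, axis=-1)
    res = StratifiedTable(stacked).test_null_odds(correction=correction)
    return TestResult(statistic=float(res.statistic), pvalue=float(res.pvalue))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, <= 1)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def neighbor_support_filter(
    candidates: Iterable[Tuple[str, int, bool]],
    window: int = 1000,
) -> List[Tuple[str, int]]:
    """Keep outlier SNPs supported by another outlier within ``window``
    bp on the same chromosome (isolated outliers are discarded)."""
    outliers: dict = {}
    for chrom, pos, is_outlier in candidates:
        if is_outlier:
            outliers.setdefault(chrom, []).append(int(pos))
    kept: List[Tuple[str, int]] = []
    for chrom, positions in outliers.items():
        pos = np.sort(np.asarray(positions))
        # a sorted outlier is supported iff an adjacent outlier is close
        left = np.empty(pos.size, dtype=bool)
        right = np.empty(pos.size, dtype=bool)
        left[0] = False
        left[1:] = (pos[1:] - pos[:-1]) <= window
        right[-1] = False
        right[:-1] = (pos[1:] - pos[:-1]) <= window
        for p in pos[left | right]:
            kept.append((chrom, int(p)))
    return sorted(kept)
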