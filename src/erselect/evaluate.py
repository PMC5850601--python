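"""Accuracy metrics and simulation experiments.

Accuracy of selection-coefficient estimates is summarised by the
relative root-mean-squared error over a set of loci,

    rRMSE = sqrt(mean((s_hat_i - s_i)^2)) / mean(s_i),

which captures both bias and variance on a scale relative to the mean
true coefficient.  The experiment runners below simulate unlinked loci
under a chosen design, estimate ``s`` with the consensus LLS pipeline,
and report rRMSE over a parameter-space grid, detection power of the
neutrality test, or the rRMSE change caused by altering one design
parameter at a time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .estimate import lls_pipeline_batch
from .significance import neutrality_test_batch
from .simulate import SimDesign, simulate_dataset

__all__ = [
    "AccuracyGrid",
    "rrmse",
    "bin_and_score",
    "clip_to_range",
    "power_experiment",
    "design_sweep",
    "estimate_dataset",
]


def rrmse(estimates, truths) -> float:
    """Relative root-mean-squared error of ``estimates`` against ``truths``.

    Undefined (raises) when the mean true coefficient is zero.
    """
    est = np.asarray(estimates, dtype=float)
    tru = np.asarray(truths, dtype=float)
    if est.shape != tru.shape or est.size == 0:
        raise ValueError("estimates and truths must be equal-length and non-empty")
    mean_s = tru.mean()
    if mean_s == 0.0:
        raise ValueError("rRMSE undefined: mean true selection coefficient is 0")
    return float(np.sqrt(np.mean((est - tru) ** 2)) / mean_s)


def clip_to_range(estimates, lo: float = -0.2, hi: float = 1.0):
    """Project estimates onto a fixed range (comparability with
    bounded-prior methods).  Idempotent."""
    if lo > hi:
        raise ValueError("lower bound exceeds upper bound")
    out = np.clip(np.asarray(estimates, dtype=float), lo, hi)
    return out


@dataclass
class AccuracyGrid:
    """Binned rRMSE over the (p0, s) parameter space."""

    p0_edges: np.ndarray
    s_edges: np.ndarray
    rrmse: np.ndarray  # (n_p0_bins, n_s_bins); NaN where undefined/empty
    n_loci: np.ndarray  # per-bin locus count
    ci_low: Optional[np.ndarray] = None
    ci_high: Optional[np.ndarray] = None

    def fraction_below(self, threshold: float) -> float:
        """Fraction of populated bins with rRMSE below ``threshold``."""
        vals = self.rrmse[np.isfinite(self.rrmse)]
        if vals.size == 0:
            return float("nan")
        return float(np.mean(vals < threshold))


def bin_and_score(
    results: pd.DataFrame,
    p0_edges=None,
    s_edges=None,
    n_bins: int = 10,
    n_boot: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> AccuracyGrid:
    """Equal-width binning of loci over (p0, s) with per-bin rRMSE.

    ``results`` needs columns ``p0``, ``s`` (truth) and ``s_hat``.  Loci
    without an estimate are dropped.  Bins with no loci, or whose mean
    true ``s`` is zero, hold NaN.  With ``n_boot > 0``, percentile
    bootstrap confidence intervals (2.5/97.5%) are attached by
    resampling loci within each bin.
    """
    df = results.dropna(subset=["s_hat"])
    if p0_edges is None:
        p0_edges = np.linspace(0.0, 1.0, n_bins + 1)
    if s_edges is None:
        s_edges = np.linspace(0.0, 0.3, n_bins + 1)
    p0_edges = np.asarray(p0_edges, dtype=float)
    s_edges = np.asarray(s_edges, dtype=float)
    ip = np.clip(np.searchsorted(p0_edges, df["p0"].to_numpy(), side="right") - 1, 0, p0_edges.size - 2)
    isx = np.clip(np.searchsorted(s_edges, df["s"].to_numpy(), side="right") - 1, 0, s_edges.size - 2)
    shape = (p0_edges.size - 1, s_edges.size - 1)
    grid = np.full(shape, np.nan)
    counts = np.zeros(shape, dtype=int)
    ci_lo = np.full(shape, np.nan) if n_boot else None
    ci_hi = np.full(shape, np.nan) if n_boot else None
    s_true = df["s"].to_numpy()
    s_hat = df["s_hat"].to_numpy()
    if rng is None:
        rng = np.random.default_rng(0)
    for i in range(shape[0]):
        in_i = ip == i
        for j in range(shape[1]):
            sel = in_i & (isx == j)
            n = int(sel.sum())
            counts[i, j] = n
            if n == 0 or s_true[sel].mean() == 0.0:
                continue
            grid[i, j] = rrmse(s_hat[sel], s_true[sel])
            if n_boot:
                e, t = s_hat[sel], s_true[sel]
                reps = np.empty(n_boot)
                for b in range(n_boot):
                    k = rng.integers(0, n, size=n)
                    tb = t[k]
                    reps[b] = np.nan if tb.mean() == 0 else rrmse(e[k], tb)
                ci_lo[i, j], ci_hi[i, j] = np.nanpercentile(reps, [2.5, 97.5])
    return AccuracyGrid(p0_edges, s_edges, grid, counts, ci_lo, ci_hi)


def estimate_dataset(
    ds,
    bias_correction: bool = True,
    weights=None,
    clip: Optional[Tuple[float, float]] = None,
) -> pd.DataFrame:
    """LLS estimates for every locus of a simulated dataset, merged with
    the truth table (columns p0, s, h, s_hat, p0_hat, n_points)."""
    res = lls_pipeline_batch(
        ds.alt, ds.cov, ds.times, ds.design.ploidy,
        bias_correction=bias_correction, weights=weights,
    )
    out = ds.truth.copy()
    s_hat = res["s_hat"]
    if clip is not None:
        s_hat = np.where(np.isfinite(s_hat), clip_to_range(s_hat, *clip), s_hat)
    out["s_hat"] = s_hat
    out["p0_hat"] = res["p0_hat"]
    out["n_points"] = res["n_points"]
    return out


def power_experiment(
    design: SimDesign,
    s_grid: Sequence,
    p0_grid: Sequence,
    alpha: float = 0.01,
    n_loci: int = 1000,
    n_sims: int = 1000,
    seed: Optional[int] = None,
    h: float = 0.5,
) -> pd.DataFrame:
    """Detection power of the bootstrap neutrality test per (s, p0) cell.

    Each grid entry may be a fixed value or a ``(lo, hi)`` uniform
    range.  Power is the fraction of simulated loci with p < alpha among
    those yielding a p-value; the count of loci without one is reported
    separately.
    """
    rows = []
    for ci, s_spec in enumerate(s_grid):
        for cj, p0_spec in enumerate(p0_grid):
            ss = np.random.SeedSequence(seed if seed is not None else 0, spawn_key=(ci, cj))
            ds = simulate_dataset(n_loci, p0_spec, s_spec, h, design, seed=int(ss.generate_state(1)[0] % 2**31))
            rng = np.random.default_rng(np.random.SeedSequence(seed if seed is not None else 0, spawn_key=(ci, cj, 1)))
            df = neutrality_test_batch(
                ds.alt, ds.cov, ds.times,
                ne=design.ne, ploidy=design.ploidy, n_sims=n_sims, rng=rng,
            )
            pv = df["pvalue"].to_numpy()
            tested = np.isfinite(pv)
            rows.append(
                {
                    "s": s_spec if np.isscalar(s_spec) else tuple(s_spec),
                    "p0": p0_spec if np.isscalar(p0_spec) else tuple(p0_spec),
                    "power": float(np.mean(pv[tested] < alpha)) if tested.any() else float("nan"),
                    "n_loci": n_loci,
                    "n_tested": int(tested.sum()),
                }
            )
    return pd.DataFrame(rows)


_SWEEPABLE = {"interval", "mean_coverage", "generations", "ne", "replicates"}


def design_sweep(
    base: SimDesign,
    parameter: str,
    values: Sequence,
    scenario: Tuple[float, float, float],
    n_loci: int = 2000,
    seed: Optional[int] = None,
    clip: Optional[Tuple[float, float]] = None,
) -> pd.DataFrame:
    """rRMSE change when one design parameter is varied.

    ``scenario`` is the fixed truth ``(p0, s, h)``.  Output rows carry
    the absolute rRMSE and its percent change relative to the base
    design's value of that parameter (0% at the base value by
    construction of the reference run).
    """
    if parameter not in _SWEEPABLE:
        raise ValueError(f"parameter must be one of {sorted(_SWEEPABLE)}")
    p0, s, h = scenario
    rows = []
    base_value = getattr(base, parameter)
    all_values = list(values)
    if base_value not in all_values:
        all_values = [base_value] + all_values
    scores = {}
    for k, val in enumerate(all_values):
        design = base.with_(**{parameter: val})
        ss = np.random.SeedSequence(seed if seed is not None else 0, spawn_key=(k,))
        ds = simulate_dataset(n_loci, p0, s, h, design, seed=int(ss.generate_state(1)[0] % 2**31))
        est = estimate_dataset(ds, clip=clip)
        ok = est.dropna(subset=["s_hat"])
        scores[val] = rrmse(ok["s_hat"], ok["s"]) if len(ok) else float("nan")
    ref = scores[base_value]
    for val in all_values:
        rows.append(
            {
                "parameter": parameter,
                "value": val,
                "rrmse": scores[val],
                "pct_change": 100.0 * (scores[val] - ref) / ref,
            }
        )
    return pd.DataFrame(rows)
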