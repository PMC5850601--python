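"""Deterministic single-locus selection dynamics.

A biallelic locus with alleles A and a evolves under constant selection in
an effectively infinite population.  Relative fitnesses are

* haploid:  ``w_A = 1 + s``, ``w_a = 1``
* diploid:  ``w_AA = 1 + s``, ``w_Aa = 1 + h*s``, ``w_aa = 1``

where ``s`` is the selection coefficient and ``h`` the dominance parameter
(``h = 0.5`` is codominance, ``h = 0`` recessive, ``h = 1`` dominant).
Diploid genotype frequencies are assumed to be at Hardy-Weinberg
proportions every generation.

For codominant selection the trajectory has a closed continuous-time form
whose logit is exactly linear in time: ``logit(p_t) = logit(p_0) + s*t``
(haploid) or ``+ (s/2)*t`` (diploid).  That linearity is the basis of the
logit-linear least-squares (LLS) estimator in :mod:`erselect.estimate`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
from scipy.special import expit

Ploidy = Literal["haploid", "diploid"]

_PLOIDIES = ("haploid", "diploid")


def _check_ploidy(ploidy: str) -> str:
    if ploidy not in _PLOIDIES:
        raise ValueError(f"ploidy must be one of {_PLOIDIES}, got {ploidy!r}")
    return ploidy


@dataclass(frozen=True)
class SelectionParams:
    """Fitness model of a locus.

    Parameters
    ----------
    s
        Selection coefficient per generation; must exceed -1 so all
        fitnesses stay positive.
    h
        Dominance parameter; ignored for haploids.  Values outside
        [0, 1] (over-/under-dominance) are accepted but flagged via
        :attr:`unusual_dominance`.
    ploidy
        ``"haploid"`` or ``"diploid"``.
    """

    s: float
    h: float = 0.5
    ploidy: Ploidy = "diploid"

    def __post_init__(self) -> None:
        if not np.isfinite(self.s) or self.s <= -1.0:
            raise ValueError(f"selection coefficient must be finite and > -1, got {self.s}")
        if not np.isfinite(self.h):
            raise ValueError(f"dominance parameter must be finite, got {self.h}")
        _check_ploidy(self.ploidy)

    @property
    def unusual_dominance(self) -> bool:
        """True for over-/under-dominance (h outside [0, 1])."""
        return self.ploidy == "diploid" and not (0.0 <= self.h <= 1.0)


@dataclass(frozen=True)
class FreqSeries:
    """Allele frequencies aligned to an increasing grid of generations."""

    generations: np.ndarray
    freqs: np.ndarray

    def __post_init__(self) -> None:
        gens = np.asarray(self.generations, dtype=int)
        freqs = np.asarray(self.freqs, dtype=float)
        if gens.ndim != 1 or freqs.ndim != 1 or gens.size != freqs.size:
            raise ValueError("generations and freqs must be 1-D and equal length")
        if gens.size and (np.any(np.diff(gens) <= 0) or gens[0] < 0):
            raise ValueError("generations must be non-negative and strictly increasing")
        with np.errstate(invalid="ignore"):
            if np.any((freqs < 0) | (freqs > 1)):
                raise ValueError("frequencies must lie in [0, 1]")
        object.__setattr__(self, "generations", gens)
        object.__setattr__(self, "freqs", freqs)

    def __len__(self) -> int:
        return int(self.generations.size)


def logit(p):
    """Natural log odds ``ln(p / (1 - p))``; defined only on (0, 1)."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("logit requires frequencies strictly inside (0, 1)")
    out = np.log(p) - np.log1p(-p)
    return float(out) if out.ndim == 0 else out


def inv_logit(x):
    """Inverse of :func:`logit` (the logistic function)."""
    out = expit(np.asarray(x, dtype=float))
    return float(out) if out.ndim == 0 else out


def _step(p, s, h, ploidy: str):
    """One generation of deterministic selection; array-safe, no validation.

    ``p``, ``s`` and ``h`` broadcast against each other.  The boundaries
    0 and 1 are absorbing (the map fixes them).
    """
    p = np.asarray(p, dtype=float)
    if ploidy == "haploid":
        num = (1.0 + s) * p
        den = num + (1.0 - p)
    else:
        w_aa = 1.0 + np.asarray(s, dtype=float)
        w_het = 1.0 + np.asarray(h, dtype=float) * s
        hom = w_aa * p * p
        het = w_het * p * (1.0 - p)
        num = hom + het
        den = hom + 2.0 * het + (1.0 - p) ** 2
    return num / den


def step_discrete(p: float, params: SelectionParams) -> float:
    """Allele frequency after one generation of selection.

    Haploid: ``p' = w_A p / (w_A p + w_a (1-p))``.  Diploid: marginal
    frequency of A after selection on Hardy-Weinberg genotype
    frequencies.  ``p = 0`` and ``p = 1`` are absorbing.
    """
    p_arr = np.asarray(p, dtype=float)
    if np.any((p_arr < 0) | (p_arr > 1)):
        raise ValueError(f"allele frequency must lie in [0, 1], got {p}")
    out = _step(p_arr, params.s, params.h, params.ploidy)
    return float(out) if out.ndim == 0 else out


def trajectory_discrete(
    p0: float, params: SelectionParams, generations: Iterable[int]
) -> FreqSeries:
    """Deterministic trajectory from iterating :func:`step_discrete`.

    ``generations`` need not be contiguous; the map is iterated once per
    generation and recorded at the requested times.
    """
    gens = np.asarray(list(generations), dtype=int)
    if gens.size == 0:
        return FreqSeries(gens, np.empty(0))
    if gens[0] < 0:
        raise ValueError("generations must be non-negative")
    wanted = set(int(t) for t in gens)
    out = {}
    p = float(np.clip(p0, None, None))
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p0 must lie in [0, 1], got {p0}")
    if 0 in wanted:
        out[0] = p
    for t in range(1, int(gens.max()) + 1):
        p = float(_step(p, params.s, params.h, params.ploidy))
        if t in wanted:
            out[t] = p
    return FreqSeries(gens, np.array([out[int(t)] for t in gens]))


def trajectory_continuous(p0, s, t, ploidy: Ploidy = "diploid"):
    """Closed-form codominant trajectory (continuous-time approximation).

    ``p_t = 1 / (1 + ((1-p0)/p0) exp(-s t))`` for haploids; diploids with
    ``h = 0.5`` replace ``s`` by ``s/2`` in the exponent.  Only valid for
    ``0 < p0 < 1`` (the logit of a boundary frequency is undefined).
    """
    _check_ploidy(ploidy)
    p0 = np.asarray(p0, dtype=float)
    if np.any((p0 <= 0) | (p0 >= 1)):
        raise ValueError("trajectory_continuous requires 0 < p0 < 1")
    rate = s if ploidy == "haploid" else s / 2.0
    out = expit(logit(p0) + rate * np.asarray(t, dtype=float))
    return float(out) if out.ndim == 0 else out


def _det_traj_batch(
    p0: np.ndarray,
    s: np.ndarray,
    h,
    ploidy: str,
    times: np.ndarray,
) -> np.ndarray:
    """Deterministic trajectories for many loci at once.

    Returns an array of shape ``(n, len(times))``; row i is the discrete
    deterministic trajectory from ``p0[i]`` with ``s[i]``.
    """
    p0 = np.atleast_1d(np.asarray(p0, dtype=float))
    s = np.broadcast_to(np.asarray(s, dtype=float), p0.shape)
    h = np.broadcast_to(np.asarray(h, dtype=float), p0.shape)
    times = np.asarray(times, dtype=int)
    out = np.empty((p0.size, times.size))
    wanted = {int(t): k for k, t in enumerate(times)}
    p = p0.copy()
    if 0 in wanted:
        out[:, wanted[0]] = p
    for t in range(1, int(times.max(initial=0)) + 1):
        p = _step(p, s, h, ploidy)
        if t in wanted:
            out[:, wanted[t]] = p
    return out
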