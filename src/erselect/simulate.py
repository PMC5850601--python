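"""Wright-Fisher forward simulation with Pool-Seq sampling noise.

Unlinked loci evolve in a population of constant effective size ``Ne``;
each generation the post-selection expected frequency (deterministic map
of :mod:`erselect.model`) is resampled binomially over the gamete pool
(``Ne`` copies for haploids, ``2*Ne`` for diploids).  Pool-Seq
observation noise is layered on top: per sample the read coverage is
drawn from a Poisson distribution and the allele count binomially at the
population (or pool) frequency.

The batch functions (:func:`simulate_trajectories`,
:func:`sample_poolseq`) vectorise over loci and replicates and are the
engine behind the parametric-bootstrap neutrality test and the
evaluation experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .model import Ploidy, SelectionParams, _check_ploidy, _step

# Loci are simulated in fixed-size blocks, each seeded from its own
# deterministic child of the root seed, so enlarging n_loci never
# reshuffles earlier loci.
_LOCUS_BLOCK = 4096


@dataclass(frozen=True)
class SimDesign:
    """Experimental design of a (simulated) E&R time series.

    Defaults follow the standard design used throughout the evaluation:
    six replicates of an ``Ne = 300`` diploid population followed for 60
    generations, allele frequencies measured every 10 generations at an
    expected Pool-Seq coverage of 80 reads.
    """

    ne: int = 300
    replicates: int = 6
    generations: int = 60
    interval: int = 10
    sampling_times: Optional[Tuple[int, ...]] = None
    mean_coverage: float = 80.0
    pool_size: Optional[int] = None
    ploidy: Ploidy = "diploid"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.ne < 1:
            raise ValueError("ne must be >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.mean_coverage <= 0:
            raise ValueError("mean_coverage must be > 0")
        _check_ploidy(self.ploidy)
        if self.sampling_times is None:
            times = tuple(range(0, self.generations + 1, self.interval))
            object.__setattr__(self, "sampling_times", times)
        else:
            times = tuple(int(t) for t in self.sampling_times)
            object.__setattr__(self, "sampling_times", times)
        times = self.sampling_times
        if not times or times[0] != 0:
            raise ValueError("sampling_times must start at generation 0")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("sampling_times must be strictly increasing")
        if times[-1] > self.generations:
            raise ValueError("sampling_times must not exceed total generations")

    @property
    def n_gametes(self) -> int:
        """Size of the binomially resampled gamete pool."""
        return self.ne if self.ploidy == "haploid" else 2 * self.ne

    @property
    def times(self) -> np.ndarray:
        return np.asarray(self.sampling_times, dtype=int)

    def with_(self, **kwargs) -> "SimDesign":
        """Copy of the design with fields replaced.

        ``generations`` and ``interval`` changes drop an explicitly
        stored sampling grid so it is re-derived.
        """
        if ("generations" in kwargs or "interval" in kwargs) and "sampling_times" not in kwargs:
            kwargs["sampling_times"] = None
        return replace(self, **kwargs)


@dataclass(frozen=True)
class PoolSample:
    """One Pool-Seq observation: reads covering the locus and how many
    carry allele A.  Zero coverage marks the observation as missing."""

    coverage: int
    alt_count: int

    def __post_init__(self) -> None:
        if not 0 <= self.alt_count <= self.coverage:
            raise ValueError("need 0 <= alt_count <= coverage")

    @property
    def missing(self) -> bool:
        return self.coverage == 0

    @property
    def freq_hat(self) -> float:
        return self.alt_count / self.coverage if self.coverage else float("nan")


@dataclass
class Trajectory:
    """Replicate x time-point observations of one locus.

    ``freqs`` holds observed allele frequencies with shape
    ``(replicates, n_times)``; NaN marks missing observations (zero
    coverage).  When the trajectory comes from Pool-Seq data, ``alt``
    and ``cov`` hold the underlying read counts.
    """

    times: np.ndarray
    freqs: np.ndarray
    alt: Optional[np.ndarray] = None
    cov: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=int)
        self.freqs = np.atleast_2d(np.asarray(self.freqs, dtype=float))
        if self.freqs.shape[1] != self.times.size:
            raise ValueError("freqs must have one column per sampling time")
        for name in ("alt", "cov"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.atleast_2d(np.asarray(arr, dtype=int))
                if arr.shape != self.freqs.shape:
                    raise ValueError(f"{name} must match freqs in shape")
                setattr(self, name, arr)

    @classmethod
    def from_counts(cls, times, alt, cov) -> "Trajectory":
        alt = np.atleast_2d(np.asarray(alt, dtype=int))
        cov = np.atleast_2d(np.asarray(cov, dtype=int))
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs = np.where(cov > 0, alt / np.maximum(cov, 1), np.nan)
        return cls(times=np.asarray(times, dtype=int), freqs=freqs, alt=alt, cov=cov)

    @property
    def n_replicates(self) -> int:
        return self.freqs.shape[0]


def wf_generation(p: float, params: SelectionParams, ne: int, rng: np.random.Generator) -> float:
    """One Wright-Fisher generation: deterministic selection followed by
    binomial resampling of the gamete pool.  0 and 1 are absorbing."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"allele frequency must lie in [0, 1], got {p}")
    n_gam = ne if params.ploidy == "haploid" else 2 * ne
    p_sel = float(_step(p, params.s, params.h, params.ploidy))
    return rng.binomial(n_gam, p_sel) / n_gam


def simulate_trajectories(
    p0,
    s,
    h,
    *,
    ne: int,
    ploidy: Ploidy,
    sampling_times,
    replicates: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Population allele-frequency trajectories for a batch of loci.

    ``p0``, ``s`` and ``h`` broadcast to a common shape ``(n,)``.
    Returns population frequencies at ``sampling_times`` with shape
    ``(n, replicates, n_times)``.  Replicates are independent chains
    started from the same ``p0``.
    """
    _check_ploidy(ploidy)
    p0 = np.atleast_1d(np.asarray(p0, dtype=float))
    s = np.broadcast_to(np.asarray(s, dtype=float), p0.shape)
    h = np.broadcast_to(np.asarray(h, dtype=float), p0.shape)
    times = np.asarray(sampling_times, dtype=int)
    n = p0.size
    n_gam = ne if ploidy == "haploid" else 2 * ne

    p = np.repeat(p0[:, None], replicates, axis=1)  # (n, R)
    s2 = s[:, None]
    h2 = h[:, None]
    out = np.empty((n, replicates, times.size))
    wanted = {int(t): k for k, t in enumerate(times)}
    if 0 in wanted:
        out[:, :, wanted[0]] = p
    for t in range(1, int(times.max(initial=0)) + 1):
        p_sel = _step(p, s2, h2, ploidy)
        p = rng.binomial(n_gam, p_sel) / n_gam
        if t in wanted:
            out[:, :, wanted[t]] = p
    return out


def sample_poolseq(
    freqs: np.ndarray,
    mean_coverage: float,
    rng: np.random.Generator,
    pool_size: Optional[int] = None,
    coverages: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Pool-Seq read sampling for an array of population frequencies.

    Coverage is Poisson(``mean_coverage``) per entry unless an explicit
    ``coverages`` array is given (used by the bootstrap to reuse observed
    coverages).  With ``pool_size`` set, an intermediate pool of that
    many individuals is drawn first (two-stage binomial).  Returns
    integer arrays ``(alt, cov)`` of the same shape as ``freqs``; entries
    with zero coverage are missing observations.
    """
    freqs = np.asarray(freqs, dtype=float)
    if coverages is None:
        cov = rng.poisson(mean_coverage, size=freqs.shape)
    else:
        cov = np.asarray(coverages, dtype=int)
        if cov.shape != freqs.shape:
            raise ValueError("coverages must match freqs in shape")
    p = freqs
    if pool_size is not None:
        p = rng.binomial(pool_size, freqs) / pool_size
    alt = rng.binomial(cov, p)
    return alt, cov


def poolseq_sample(
    p: float,
    mean_coverage: float,
    rng: np.random.Generator,
    pool_size: Optional[int] = None,
) -> PoolSample:
    """Single Pool-Seq observation of a population frequency ``p``."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"allele frequency must lie in [0, 1], got {p}")
    alt, cov = sample_poolseq(np.array([p]), mean_coverage, rng, pool_size=pool_size)
    return PoolSample(coverage=int(cov[0]), alt_count=int(alt[0]))


def simulate_locus(
    p0: float,
    params: SelectionParams,
    design: SimDesign,
    rng: Optional[np.random.Generator] = None,
) -> Trajectory:
    """Replicated population frequencies of a single locus (no
    observation noise; apply :func:`sample_poolseq` for Pool-Seq)."""
    if rng is None:
        rng = np.random.default_rng(design.seed)
    freqs = simulate_trajectories(
        p0,
        params.s,
        params.h,
        ne=design.ne,
        ploidy=design.ploidy,
        sampling_times=design.times,
        replicates=design.replicates,
        rng=rng,
    )[0]
    return Trajectory(times=design.times, freqs=freqs)


def _draw_param(spec, n: int, rng: np.random.Generator) -> np.ndarray:
    """A fixed value or a (lo, hi) uniform range, drawn for n loci."""
    if np.isscalar(spec):
        return np.full(n, float(spec))
    lo, hi = spec
    return rng.uniform(lo, hi, size=n)


@dataclass
class SimulatedDataset:
    """Truth and Pool-Seq observations for a set of simulated loci."""

    design: SimDesign
    truth: pd.DataFrame  # columns: locus, p0, s, h
    freqs: np.ndarray  # population frequencies (n, R, T)
    alt: np.ndarray  # observed allele read counts (n, R, T)
    cov: np.ndarray  # observed coverages (n, R, T)

    @property
    def times(self) -> np.ndarray:
        return self.design.times

    @property
    def n_loci(self) -> int:
        return len(self.truth)

    def trajectory(self, i: int) -> Trajectory:
        return Trajectory.from_counts(self.times, self.alt[i], self.cov[i])


def simulate_dataset(
    n_loci: int,
    p0_dist,
    s_dist,
    h: float,
    design: SimDesign,
    seed: Optional[int] = None,
) -> SimulatedDataset:
    """Simulate ``n_loci`` unlinked loci under one design.

    ``p0_dist`` and ``s_dist`` are either fixed values or ``(lo, hi)``
    uniform ranges.  Loci are generated in fixed-size blocks with
    per-block RNG streams derived from the root seed, so the first k
    loci are identical regardless of ``n_loci``.
    """
    if seed is None:
        seed = design.seed
    T = design.times.size
    R = design.replicates
    p0_all = np.empty(n_loci)
    s_all = np.empty(n_loci)
    freqs = np.empty((n_loci, R, T))
    alt = np.empty((n_loci, R, T), dtype=int)
    cov = np.empty((n_loci, R, T), dtype=int)
    n_blocks = max(1, -(-n_loci // _LOCUS_BLOCK))
    for b in range(n_blocks):
        lo = b * _LOCUS_BLOCK
        hi = min(n_loci, lo + _LOCUS_BLOCK)
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(b,)))
        # always draw a full block so earlier loci are stable in n_loci
        p0_b = _draw_param(p0_dist, _LOCUS_BLOCK, rng)
        s_b = _draw_param(s_dist, _LOCUS_BLOCK, rng)
        f_b = simulate_trajectories(
            p0_b,
            s_b,
            h,
            ne=design.ne,
            ploidy=design.ploidy,
            sampling_times=design.times,
            replicates=R,
            rng=rng,
        )
        a_b, c_b = sample_poolseq(
            f_b, design.mean_coverage, rng, pool_size=design.pool_size
        )
        k = hi - lo
        p0_all[lo:hi] = p0_b[:k]
        s_all[lo:hi] = s_b[:k]
        freqs[lo:hi] = f_b[:k]
        alt[lo:hi] = a_b[:k]
        cov[lo:hi] = c_b[:k]
    truth = pd.DataFrame(
        {
            "locus": np.arange(n_loci),
            "p0": p0_all,
            "s": s_all,
            "h": np.full(n_loci, float(h)),
        }
    )
    return SimulatedDataset(design=design, truth=truth, freqs=freqs, alt=alt, cov=cov)
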