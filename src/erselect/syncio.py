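"""Reading and writing Pool-Seq count formats.

The sync format (PoPoolation2 dialect) is tab-separated with columns
``chrom``, ``pos`` (1-based), ``ref`` and then one column per sample
holding ``A:T:C:G:N:del`` read counts.  Sync files carry no metadata
about which sample is which, so a *layout* — an ordered list of
``(replicate, time)`` labels, one per sample column — must accompany
them.

For each locus the two bases with the highest pooled counts form the
biallelic pair (ties broken in A<T<C<G order); loci with more than two
segregating bases above a noise floor are skipped.  The tracked
("rising") allele is the pair member whose pooled frequency increases
from the first to the last time point, falling back to the non-reference
member on ties.  Coverage counts A+T+C+G reads only; N and deletion
counts never contribute.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .simulate import SimulatedDataset, Trajectory

__all__ = [
    "SyncRecord",
    "LocusSeries",
    "read_sync_records",
    "read_sync",
    "write_sync",
    "dataset_to_sync",
    "write_trajectories_tsv",
    "read_trajectories_tsv",
]

_BASES = "ATCG"


@dataclass(frozen=True)
class SyncRecord:
    """One sync line: position plus per-sample A:T:C:G:N:del counts."""

    chrom: str
    pos: int
    ref: str
    samples: Tuple[Tuple[int, int, int, int, int, int], ...]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("sync positions are 1-based (pos >= 1)")
        for tup in self.samples:
            if len(tup) != 6 or any(c < 0 for c in tup):
                raise ValueError("each sample needs six non-negative counts")


@dataclass
class LocusSeries:
    """Replicate x time read counts of the tracked allele at one locus."""

    chrom: str
    pos: int
    rising: str
    other: str
    times: np.ndarray  # (T,)
    replicates: np.ndarray  # (R,) replicate labels
    alt: np.ndarray  # (R, T) reads carrying the rising allele
    cov: np.ndarray  # (R, T) A+T+C+G reads

    def trajectory(self) -> Trajectory:
        return Trajectory.from_counts(self.times, self.alt, self.cov)

    @property
    def locus_id(self) -> str:
        return f"{self.chrom}:{self.pos}"


def _parse_count_field(field: str, lineno: int):
    parts = field.split(":")
    if len(parts) != 6:
        raise ValueError(f"line {lineno}: malformed count field {field!r} (need A:T:C:G:N:del)")
    try:
        counts = tuple(int(x) for x in parts)
    except ValueError as exc:
        raise ValueError(f"line {lineno}: non-integer count in {field!r}") from exc
    if any(c < 0 for c in counts):
        raise ValueError(f"line {lineno}: negative count in {field!r}")
    return counts


def read_sync_records(path) -> List[SyncRecord]:
    """Parse a sync file into raw records (no layout interpretation)."""
    records: List[SyncRecord] = []
    opener = open(path) if not isinstance(path, io.TextIOBase) else path
    with opener as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"line {lineno}: need chrom, pos, ref and >= 1 sample column")
            chrom, pos, ref = fields[0], int(fields[1]), fields[2]
            samples = tuple(_parse_count_field(f, lineno) for f in fields[3:])
            records.append(SyncRecord(chrom=chrom, pos=pos, ref=ref, samples=samples))
    return records


def write_sync(records: Iterable[SyncRecord], path) -> None:
    """Write records in the same dialect, in the given order."""
    own = not isinstance(path, io.TextIOBase)
    fh = open(path, "w") if own else path
    try:
        for rec in records:
            cols = [rec.chrom, str(rec.pos), rec.ref]
            cols += [":".join(str(c) for c in tup) for tup in rec.samples]
            fh.write("\t".join(cols) + "\n")
    finally:
        if own:
            fh.close()


def _normalise_layout(layout, n_samples: int) -> List[Tuple[int, int]]:
    if isinstance(layout, dict):
        pairs = [layout[i] for i in range(n_samples)]
    else:
        pairs = list(layout)
    if len(pairs) != n_samples:
        raise ValueError(f"layout covers {len(pairs)} columns but file has {n_samples} samples")
    return [(int(r), int(t)) for r, t in pairs]


def read_sync(path, layout, noise_floor_frac: float = 0.01) -> List[LocusSeries]:
    """Load a sync file into per-locus replicate x time count series.

    ``layout`` assigns each sample column a ``(replicate, time)`` pair
    (ordered list, or a dict keyed by 0-based column index).  Every
    replicate must be observed at every time of the layout's grid.
    Loci with more than two bases above the noise floor (a pooled count
    exceeding ``noise_floor_frac`` of pooled coverage, minimum 2 reads)
    are skipped as multiallelic.
    """
    records = read_sync_records(path)
    if not records:
        return []
    pairs = _normalise_layout(layout, len(records[0].samples))
    reps = np.array(sorted({r for r, _ in pairs}))
    times = np.array(sorted({t for _, t in pairs}))
    index = {}
    for col, (r, t) in enumerate(pairs):
        key = (int(np.searchsorted(reps, r)), int(np.searchsorted(times, t)))
        if key in index:
            raise ValueError(f"layout assigns two columns to replicate {r}, time {t}")
        index[key] = col
    if len(index) != reps.size * times.size:
        raise ValueError("layout must cover every replicate at every time point")

    out: List[LocusSeries] = []
    for rec in records:
        if len(rec.samples) != len(pairs):
            raise ValueError(f"{rec.chrom}:{rec.pos}: sample column count differs from layout")
        counts = np.asarray(rec.samples, dtype=int)[:, :4]  # A T C G
        pooled = counts.sum(axis=0)
        total = int(pooled.sum())
        floor = max(2, int(np.ceil(noise_floor_frac * total)))
        segregating = int(np.sum(pooled >= floor))
        if segregating > 2:
            continue  # multiallelic locus
        order = np.lexsort((np.arange(4), -pooled))  # by count desc, ties A<T<C<G
        a_idx, b_idx = int(order[0]), int(order[1])
        a, b = _BASES[a_idx], _BASES[b_idx]
        # polarise: rising allele gains pooled frequency first -> last time
        t_first = [index[(ri, 0)] for ri in range(reps.size)]
        t_last = [index[(ri, times.size - 1)] for ri in range(reps.size)]
        c_first = counts[t_first].sum(axis=0)
        c_last = counts[t_last].sum(axis=0)

        def _freq(c, idx):
            tot = c[a_idx] + c[b_idx]
            return c[idx] / tot if tot else 0.0

        delta = _freq(c_last, a_idx) - _freq(c_first, a_idx)
        if delta > 0:
            rising_idx, other_idx = a_idx, b_idx
        elif delta < 0:
            rising_idx, other_idx = b_idx, a_idx
        elif rec.ref == a:
            rising_idx, other_idx = b_idx, a_idx  # tie: ref-alt orientation
        else:
            rising_idx, other_idx = a_idx, b_idx
        alt = np.empty((reps.size, times.size), dtype=int)
        cov = np.empty((reps.size, times.size), dtype=int)
        for ri in range(reps.size):
            for ti in range(times.size):
                c = counts[index[(ri, ti)]]
                alt[ri, ti] = c[rising_idx]
                cov[ri, ti] = int(c.sum())
        out.append(
            LocusSeries(
                chrom=rec.chrom, pos=rec.pos,
                rising=_BASES[rising_idx], other=_BASES[other_idx],
                times=times, replicates=reps, alt=alt, cov=cov,
            )
        )
    return out


def dataset_to_sync(ds: SimulatedDataset, ref: str = "A", rising: str = "T"):
    """Express a simulated dataset as sync records plus the layout.

    The tracked allele is written as ``rising`` and the remaining reads
    as the reference base; loci become consecutive 1-based positions on
    a synthetic chromosome.  Returns ``(records, layout)`` with sample
    columns ordered replicate-major.
    """
    if ref == rising:
        raise ValueError("ref and rising bases must differ")
    i_ref, i_alt = _BASES.index(ref), _BASES.index(rising)
    R, T = ds.design.replicates, ds.times.size
    layout = [(r, int(t)) for r in range(R) for t in ds.times]
    records = []
    for i in range(ds.n_loci):
        samples = []
        for r in range(R):
            for ti in range(T):
                counts = [0, 0, 0, 0, 0, 0]
                counts[i_alt] = int(ds.alt[i, r, ti])
                counts[i_ref] = int(ds.cov[i, r, ti] - ds.alt[i, r, ti])
                samples.append(tuple(counts))
        records.append(SyncRecord(chrom="sim", pos=i + 1, ref=ref, samples=tuple(samples)))
    return records, layout


_TSV_COLS = ["locus", "replicate", "time", "alt_count", "coverage"]


def write_trajectories_tsv(series: Sequence[LocusSeries], path, header_comment: Optional[str] = None) -> None:
    """Long-format TSV: locus, replicate, time, alt_count, coverage."""
    rows = []
    for ls in series:
        for ri, r in enumerate(ls.replicates):
            for ti, t in enumerate(ls.times):
                rows.append((ls.locus_id, int(r), int(t), int(ls.alt[ri, ti]), int(ls.cov[ri, ti])))
    df = pd.DataFrame(rows, columns=_TSV_COLS)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_trajectories_tsv(path) -> List[LocusSeries]:
    """Inverse of :func:`write_trajectories_tsv` (rising/other unknown)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in _TSV_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory TSV lacks columns {missing}")
    out = []
    for locus, grp in df.groupby("locus", sort=False):
        reps = np.array(sorted(grp["replicate"].unique()))
        times = np.array(sorted(grp["time"].unique()))
        alt = np.zeros((reps.size, times.size), dtype=int)
        cov = np.zeros((reps.size, times.size), dtype=int)
        seen = np.zeros((reps.size, times.size), dtype=bool)
        for _, row in grp.iterrows():
            ri = int(np.searchsorted(reps, row["replicate"]))
            ti = int(np.searchsorted(times, row["time"]))
            alt[ri, ti] = int(row["alt_count"])
            cov[ri, ti] = int(row["coverage"])
            seen[ri, ti] = True
        if not seen.all():
            raise ValueError(f"locus {locus}: incomplete replicate x time grid")
        chrom, _, pos = str(locus).partition(":")
        out.append(
            LocusSeries(
                chrom=chrom, pos=int(pos) if pos else 0, rising="?", other="?",
                times=times, replicates=reps, alt=alt, cov=cov,
            )
        )
    return out
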