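"""FT density tracks and read-subsampling saturation curves.

Density counts FT midpoints in sliding windows (default 500 kb window,
100 kb step, the scale at which break density aligns with cytogenetic
fragile-site bands).  The saturation curve re-calls FT on random read
subsets of decreasing size and reports the fraction of full-data FT
still recovered; a plateau near 100% of reads indicates the library was
sequenced to saturation.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .ft import ForumTerminus, call_ft
from .reads import MappedRead

logger = logging.getLogger(__name__)

#: 1% steps from 100% down to 70%, then 5% steps down to 10%
DEFAULT_SCHEDULE: tuple[int, ...] = tuple(range(100, 69, -1)) + tuple(range(65, 9, -5))


@dataclass(frozen=True)
class DensityTrack:
    chrom: str
    window: int
    step: int
    #: (window_start, FT count) per window, covering [0, chrom_length)
    values: tuple[tuple[int, int], ...]


def ft_density(
    ft: Sequence[ForumTerminus],
    chrom_sizes: Mapping[str, int],
    window: int = 500_000,
    step: int = 100_000,
) -> dict[str, DensityTrack]:
    """Count FT per sliding window on each chromosome.

    An FT is counted in a window when its midpoint lies in
    [window_start, window_start + window); counting by midpoint keeps a
    non-overlapping tiling (step == window) conservative: counts sum to
    the total number of FT.  The last window may be truncated by the
    chromosome end.
    """
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    if step > window:
        raise ValueError("step must be <= window")
    mids: dict[str, list[int]] = {c: [] for c in chrom_sizes}
    for t in ft:
        if t.chrom in mids:
            mids[t.chrom].append(t.midpoint)

    tracks: dict[str, DensityTrack] = {}
    for chrom, length in chrom_sizes.items():
        m = np.sort(np.array(mids[chrom], dtype=np.int64))
        starts = np.arange(0, length, step, dtype=np.int64)
        lo = np.searchsorted(m, starts, side="left")
        hi = np.searchsorted(m, np.minimum(starts + window, length), side="left")
        values = tuple((int(s), int(c)) for s, c in zip(starts, hi - lo))
        tracks[chrom] = DensityTrack(chrom, window, step, values)
    return tracks


def export_wig(tracks: Mapping[str, DensityTrack], path: str | os.PathLike) -> None:
    """Write tracks as fixedStep WIG (1-based starts, span = step)."""
    with open(path, "w") as fh:
        for chrom in tracks:
            tr = tracks[chrom]
            fh.write(
                f"fixedStep chrom={tr.chrom} start=1 step={tr.step} span={tr.step}\n"
            )
            for _, count in tr.values:
                fh.write(f"{count}\n")


def parse_wig(path: str | os.PathLike) -> dict[str, list[tuple[int, float]]]:
    """Minimal fixedStep WIG reader: per chromosome, (1-based start, value)."""
    out: dict[str, list[tuple[int, float]]] = {}
    chrom, start, step = None, 1, 1
    pos = 1
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            if line.startswith("fixedStep"):
                kv = dict(f.split("=", 1) for f in line.split()[1:])
                chrom = kv["chrom"]
                start = int(kv.get("start", 1))
                step = int(kv.get("step", 1))
                pos = start
                out.setdefault(chrom, [])
            else:
                if chrom is None:
                    raise ValueError(f"{path}: data line before any fixedStep header")
                out[chrom].append((pos, float(line)))
                pos += step
    return out


@dataclass(frozen=True)
class SaturationCurve:
    #: (read percent retained, percent of full-data FT recovered)
    points: tuple[tuple[float, float], ...]
    schedule: tuple[int, ...]
    seed: int


def _recovered_fraction(
    full: Sequence[ForumTerminus], sub: Sequence[ForumTerminus]
) -> float:
    """Fraction of full-data FT overlapped by at least one subsample FT."""
    if not full:
        return 100.0
    sub_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {t.chrom for t in sub}:
        ts = sorted((t for t in sub if t.chrom == chrom), key=lambda t: t.start)
        sub_by_chrom[chrom] = (
            np.array([t.start for t in ts]),
            np.array([t.end for t in ts]),
        )
    hit = 0
    for t in full:
        if t.chrom not in sub_by_chrom:
            continue
        starts, ends = sub_by_chrom[t.chrom]
        i = np.searchsorted(starts, t.end, side="left")
        # any subsample FT with start < t.end and end > t.start overlaps
        if i > 0 and ends[:i].max() > t.start:
            hit += 1
    return 100.0 * hit / len(full)


def saturation_curve(
    reads: Sequence[MappedRead],
    schedule: Optional[Sequence[int]] = None,
    seed: int = 0,
    min_gap: int = 0,
) -> SaturationCurve:
    """Recovery of FT under read subsampling.

    For each percentage in the schedule, a seeded subsample of the reads
    (without replacement, an independent substream per schedule point) is
    re-merged into FT and scored against the full-data FT; an FT counts
    as recovered when any subsample FT overlaps it.  The 100% point is
    the identity subsample and always reports 100.
    """
    sched = tuple(schedule) if schedule is not None else DEFAULT_SCHEDULE
    if any(not 0 < p <= 100 for p in sched):
        raise ValueError("schedule percentages must lie in (0, 100]")
    full = call_ft(reads, min_gap=min_gap)
    n = len(reads)
    points: list[tuple[float, float]] = []
    for k, pct in enumerate(sched):
        if pct == 100:
            points.append((100.0, 100.0))
            continue
        rng = np.random.default_rng([seed, k])
        take = int(round(n * pct / 100.0))
        if take == 0:
            points.append((float(pct), 0.0))
            continue
        idx = rng.choice(n, size=take, replace=False)
        sub = call_ft([reads[i] for i in idx], min_gap=min_gap)
        points.append((float(pct), _recovered_fraction(full, sub)))
    logger.info("saturation curve over %d schedule points (%d reads)", len(sched), n)
    return SaturationCurve(points=tuple(points), schedule=sched, seed=seed)


def write_saturation_tsv(curve: SaturationCurve, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("read_percent\tft_percent\n")
        for p, f in curve.points:
            fh.write(f"{p:g}\t{f:.4f}\n")
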