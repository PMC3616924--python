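"""Forum-terminus (FT) calling.

An FT is the maximal union of overlapping mapped reads at a break site:
one side of the interval is set by the break itself, the other by the
nearest Sau3A site, so recurrently broken positions accumulate stacks of
overlapping reads.  FT supported by at least ``min_support`` reads are
flagged as break hot spots.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .reads import MappedRead

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ForumTerminus:
    chrom: str
    start: int
    end: int
    read_count: int
    #: distinct break coordinates of the merged reads, sorted
    cut_positions: tuple[int, ...]
    hotspot: bool = False

    def __post_init__(self) -> None:
        if self.end - self.start < 1:
            raise ValueError(f"FT [{self.start},{self.end}) has non-positive length")
        if self.read_count < 1:
            raise ValueError("FT must be supported by at least one read")
        if any(not (self.start <= c <= self.end) for c in self.cut_positions):
            raise ValueError("cut positions must lie within the FT interval")

    @property
    def cut_span(self) -> int:
        """Spread of the distinct break positions (0 when there is one)."""
        if not self.cut_positions:
            return 0
        return max(self.cut_positions) - min(self.cut_positions)

    @property
    def name(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def call_ft(reads: Sequence[MappedRead], min_gap: int = 0) -> list[ForumTerminus]:
    """Merge mapped reads into FT.

    Reads merge into one FT when their intervals overlap by at least one
    base; with ``min_gap > 0`` reads separated by a gap <= min_gap also
    merge.  Reads from both strands merge together (the two flanks of a
    break).  Output is sorted and non-overlapping; the sum of FT read
    counts equals the number of input reads.
    """
    by_chrom: dict[str, list[MappedRead]] = {}
    for r in reads:
        by_chrom.setdefault(r.chrom, []).append(r)

    out: list[ForumTerminus] = []
    for chrom in sorted(by_chrom):
        rs = sorted(by_chrom[chrom], key=lambda r: (r.start, r.end))
        cur_start, cur_end = rs[0].start, rs[0].end
        cur_cuts = {rs[0].cut_position}
        cur_n = 1
        for r in rs[1:]:
            gap = r.start - cur_end
            merge = gap < 0 or (min_gap > 0 and gap <= min_gap)
            if merge:
                cur_end = max(cur_end, r.end)
                cur_cuts.add(r.cut_position)
                cur_n += 1
            else:
                out.append(
                    ForumTerminus(chrom, cur_start, cur_end, cur_n, tuple(sorted(cur_cuts)))
                )
                cur_start, cur_end = r.start, r.end
                cur_cuts = {r.cut_position}
                cur_n = 1
        out.append(ForumTerminus(chrom, cur_start, cur_end, cur_n, tuple(sorted(cur_cuts))))
    return out


def classify_hotspots(ft: Sequence[ForumTerminus], min_support: int = 2) -> list[ForumTerminus]:
    """Flag FT supported by >= min_support reads as break hot spots."""
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    flagged = [replace(t, hotspot=t.read_count >= min_support) for t in ft]
    n_hot = sum(t.hotspot for t in flagged)
    logger.info(
        "hot-spot classification (support >= %d): %d flagged, %d unflagged",
        min_support,
        n_hot,
        len(flagged) - n_hot,
    )
    return flagged


# --- export / import -------------------------------------------------------

def ft_to_bed(ft: Iterable[ForumTerminus]) -> list[str]:
    """BED6 lines: name = chrom:start-end, score = read count."""
    return [f"{t.chrom}\t{t.start}\t{t.end}\t{t.name}\t{t.read_count}\t." for t in ft]


def ft_to_gff3(ft: Iterable[ForumTerminus]) -> list[str]:
    """GFF3 lines (1-based inclusive) carrying the full FT record."""
    lines = ["##gff-version 3"]
    for t in ft:
        attrs = (
            f"ID={t.name};read_count={t.read_count};"
            f"cut_positions={','.join(map(str, t.cut_positions))};"
            f"hotspot={'true' if t.hotspot else 'false'}"
        )
        lines.append(
            f"{t.chrom}\tforumdomains\tforum_terminus\t{t.start + 1}\t{t.end}\t"
            f"{t.read_count}\t.\t.\t{attrs}"
        )
    return lines


def write_ft_bed(ft: Iterable[ForumTerminus], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(ft_to_bed(ft)) + "\n")


def write_ft_gff3(ft: Iterable[ForumTerminus], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(ft_to_gff3(ft)) + "\n")


def load_ft_gff3(path: str | os.PathLike) -> list[ForumTerminus]:
    """Lossless inverse of :func:`write_ft_gff3`."""
    out: list[ForumTerminus] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            chrom, start1, end = fields[0], int(fields[3]), int(fields[4])
            attrs = dict(kv.split("=", 1) for kv in fields[8].split(";") if kv)
            cuts = tuple(
                int(c) for c in attrs.get("cut_positions", "").split(",") if c
            )
            out.append(
                ForumTerminus(
                    chrom=chrom,
                    start=start1 - 1,
                    end=end,
                    read_count=int(attrs["read_count"]),
                    cut_positions=cuts,
                    hotspot=attrs.get("hotspot") == "true",
                )
            )
    return out


def load_ft_bed(path: str | os.PathLike) -> list[ForumTerminus]:
    """Load FT from BED6 (read count from the score column; no cut detail)."""
    out: list[ForumTerminus] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            count = int(fields[4]) if len(fields) > 4 else 1
            out.append(ForumTerminus(chrom, start, end, count, ()))
    return out
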