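"""Read clean-up and alignment loading.

Raw reads from the break-capture library carry a blunt-end adaptor at the
break (DSB) end and a Sau3A adaptor at the restriction end.  Clean-up
removes any primer/adaptor found at either read end within a small
positional window (default 5 bp from the end), then discards reads
shorter than 18 bp.  Mapped read intervals are consumed as BED; the
alignment step itself (an external mapper) is out of scope.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Which interval end carries the break, by alignment strand.  A read is
#: sequenced from the ligated blunt-end adaptor, so a forward ('+')
#: alignment has the break at its 5'-most (left) coordinate and a reverse
#: ('-') alignment at its right coordinate.  Configurable because the
#: convention is a property of the upstream mapping, not of this package.
DEFAULT_CUT_SIDE_CONVENTION: Mapping[str, str] = {"+": "left", "-": "right"}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RawRead:
    """One unprocessed sequencing read."""

    id: str
    sequence: str
    quality: Optional[Sequence[int]] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.id!r} has an empty sequence")
        bad = set(self.sequence.upper()) - set("ACGTN")
        if bad:
            raise ValueError(f"read {self.id!r} has non-nucleotide characters {bad}")


@dataclass(frozen=True)
class TrimSpec:
    """Positional primer-trimming rule.

    A primer (or its reverse complement) is searched at each read end at
    start offsets 0..max_offset from that end; on a match the primer and
    everything between it and the end are removed.
    """

    primers: tuple[str, ...]
    max_offset: int = 5
    max_mismatches: int = 0
    min_len: int = 18

    def __post_init__(self) -> None:
        if not self.primers or any(not p for p in self.primers):
            raise ValueError("primers must be a non-empty list of non-empty strings")
        if self.max_offset < 0:
            raise ValueError("max_offset must be >= 0")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")


@dataclass(frozen=True)
class TrimmedRead:
    id: str
    sequence: str
    #: bases removed from the 5' end (primer + leading offset), 0 if untrimmed
    left_trim: int = 0
    #: bases removed from the 3' end, 0 if untrimmed
    right_trim: int = 0


@dataclass(frozen=True)
class MappedRead:
    """One aligned read interval; records which end is the break."""

    chrom: str
    start: int
    end: int
    strand: str
    cut_side: str  # 'left' | 'right'
    read_id: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"read {self.read_id!r}: invalid interval [{self.start},{self.end})"
            )
        if self.cut_side not in ("left", "right"):
            raise ValueError(f"cut_side must be 'left' or 'right', got {self.cut_side!r}")

    @property
    def cut_position(self) -> int:
        """Break coordinate: the left interval edge or the right (half-open) edge."""
        return self.start if self.cut_side == "left" else self.end


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _match_at(seq: str, pos: int, primer: str, max_mismatches: int) -> bool:
    if pos < 0 or pos + len(primer) > len(seq):
        return False
    return _mismatches(seq[pos : pos + len(primer)], primer) <= max_mismatches


def trim_primers(read: RawRead, spec: TrimSpec) -> TrimmedRead:
    """Trim primers found near either read end under the positional rule.

    The 5' end is scanned first (offsets 0..max_offset, primers in the
    given order, each with its reverse complement); the 3' end is then
    scanned on the remainder.  The first match at the smallest offset
    wins.  Reads without a match pass through untouched.
    """
    seq = read.sequence.upper()
    variants = []
    for p in spec.primers:
        p = p.upper()
        variants.append(p)
        rc = reverse_complement(p)
        if rc != p:
            variants.append(rc)

    left_trim = 0
    for off in range(spec.max_offset + 1):
        hit = next((v for v in variants if _match_at(seq, off, v, spec.max_mismatches)), None)
        if hit is not None:
            left_trim = off + len(hit)
            break
    seq = seq[left_trim:]

    right_trim = 0
    n = len(seq)
    for off in range(spec.max_offset + 1):
        hit = next(
            (v for v in variants if _match_at(seq, n - off - len(v), v, spec.max_mismatches)),
            None,
        )
        if hit is not None:
            right_trim = off + len(hit)
            break
    seq = seq[: n - right_trim] if right_trim else seq

    return TrimmedRead(id=read.id, sequence=seq, left_trim=left_trim, right_trim=right_trim)


def filter_short(
    reads: Iterable[TrimmedRead], min_len: int = 18
) -> tuple[list[TrimmedRead], int]:
    """Drop reads shorter than ``min_len``; returns (kept, dropped_count)."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    kept, dropped = [], 0
    for r in reads:
        if len(r.sequence) >= min_len:
            kept.append(r)
        else:
            dropped += 1
    logger.info("length filter (>=%d bp): kept %d, dropped %d", min_len, len(kept), dropped)
    return kept, dropped


def load_alignments(
    path: str | os.PathLike,
    chrom_sizes: Mapping[str, int],
    cut_side_convention: Mapping[str, str] = DEFAULT_CUT_SIDE_CONVENTION,
) -> list[MappedRead]:
    """Load mapped read intervals from a BED file.

    Coordinates are validated against ``chrom_sizes``.  Out-of-bounds
    intervals and unknown chromosomes raise with the offending line
    number; structurally malformed lines (too few fields, non-integer
    coordinates) are counted, reported and skipped.
    """
    reads: list[MappedRead] = []
    malformed = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                malformed += 1
                continue
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                malformed += 1
                continue
            chrom = fields[0]
            if chrom not in chrom_sizes:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start in [{start},{end})")
            if start < 0 or end > chrom_sizes[chrom]:
                raise ValueError(
                    f"{path}:{lineno}: interval [{start},{end}) outside {chrom} "
                    f"(length {chrom_sizes[chrom]})"
                )
            name = fields[3] if len(fields) > 3 else f"read{lineno}"
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "+"
            reads.append(
                MappedRead(
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    cut_side=cut_side_convention[strand],
                    read_id=name,
                )
            )
    if malformed:
        logger.warning("%s: skipped %d malformed line(s)", path, malformed)
    return reads


def write_alignments_bed(reads: Iterable[MappedRead], path: str | os.PathLike) -> None:
    """Write mapped reads as BED6; strand encodes the cut side ('+' = left)."""
    with open(path, "w") as fh:
        for r in reads:
            strand = "+" if r.cut_side == "left" else "-"
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.read_id}\t0\t{strand}\n")


def write_trim_report(
    original: Sequence[RawRead], trimmed: Sequence[TrimmedRead], path: str | os.PathLike
) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\traw_len\ttrimmed_len\tleft_trim\tright_trim\n")
        for raw, t in zip(original, trimmed):
            fh.write(
                f"{t.id}\t{len(raw.sequence)}\t{len(t.sequence)}\t{t.left_trim}\t{t.right_trim}\n"
            )
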