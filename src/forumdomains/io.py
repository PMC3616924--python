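"""Small text-format readers and writers shared across the pipeline.

All in-memory coordinates follow the BED convention (0-based, half-open).
GFF3 is converted to 1-based inclusive on the way out and back on the way
in; WIG fixedStep is 1-based.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Mapping


def read_chrom_sizes(path: str | os.PathLike) -> dict[str, int]:
    """Read a two-column <name> <length> TSV into a dict."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, got {line!r}")
            sizes[fields[0]] = int(fields[1])
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, length in sizes.items():
            fh.write(f"{name}\t{length}\n")


def write_lines(lines: Iterable[str], path: str | os.PathLike) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in lines:
            fh.write(line)
            if not line.endswith("\n"):
                fh.write("\n")
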