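"""Synthetic genomes, break libraries and coordinated expression tables.

The generator emulates the experimental design of genome-wide blunt-end
double-strand-break (DSB) mapping:

* chromosomes carry recurrent break **hot spots** whose spacing is drawn
  log-normal — genome-wide the inter-hot-spot domains have a long right
  tail with a median around 110 kb;
* each break releases up to two restriction fragments, one per flank,
  each running from the cut to the nearest Sau3A (GATC) site on that
  side (expected spacing 256 bp in random sequence) and truncated to the
  maximum read length measured from the cut end;
* read sequences are decorated with the blunt-end adaptor at the cut end
  and the Sau3A adaptor at the restriction end;
* per-gene expression is coordinated at the domain level: ~30% of
  domains are active (shared positive log2 baseline), the rest sit at a
  silent floor, and genes add independent noise around their domain's
  baseline.

Every output is a deterministic function of the configuration seed.
Ground truth (hot spots, domains, alignments) is returned alongside the
reads so that downstream calling can be scored exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import os
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .reads import MappedRead
from .segmentation import ForumDomain

logger = logging.getLogger(__name__)

#: ligated to the blunt (break) end of each fragment
DSB_ADAPTOR = "GTAATACGACTCACTATAGGGC"
#: ligated to the Sau3A overhang; begins with the GATC site itself
SAU3A_ADAPTOR = "GATCGGAAGAGCACACGTCTGA"

# independent PRNG streams per stage, combined with the user seed
_STREAM_GENOME = 11
_STREAM_READS = 12
_STREAM_EXPRESSION = 13


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the simulator.

    Lengths are in bp, expression effects in log2 units.  Defaults match
    the mapped data the simulator emulates: ~110 kb median hot-spot
    spacing, 50-300 bp reads, GATC every 256 bp in expectation, ~30% of
    domains transcriptionally active.
    """

    chrom_lengths: Mapping[str, int]
    hotspot_spacing_median: int = 110_000
    hotspot_spacing_logsd: float = 1.1
    reads_per_hotspot_mean: float = 20.0
    background_break_rate: float = 1e-7
    cut_jitter_sd: float = 15.0
    sau3a_spacing_mean: float = 256.0
    read_min_len: int = 50
    read_max_len: int = 300
    #: per-break probability that each flank yields a sequenced fragment
    side_capture_prob: float = 0.5
    frac_active_domains: float = 0.30
    domain_effect_sd: float = 2.0
    gene_noise_sd: float = 0.5
    genes_per_domain_mean: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.chrom_lengths:
            raise ValueError("chrom_lengths must not be empty")
        if any(l <= 0 for l in self.chrom_lengths.values()):
            raise ValueError("chromosome lengths must be strictly positive")
        for name in (
            "hotspot_spacing_median",
            "hotspot_spacing_logsd",
            "reads_per_hotspot_mean",
            "cut_jitter_sd",
            "sau3a_spacing_mean",
            "read_min_len",
            "read_max_len",
            "genes_per_domain_mean",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.background_break_rate < 0:
            raise ValueError("background_break_rate must be >= 0")
        if not 0.0 <= self.frac_active_domains <= 1.0:
            raise ValueError("frac_active_domains must be in [0,1]")
        if not 0.0 <= self.side_capture_prob <= 1.0:
            raise ValueError("side_capture_prob must be in [0,1]")
        if self.read_min_len >= self.read_max_len:
            raise ValueError("read_min_len must be < read_max_len")


@dataclass(frozen=True)
class Hotspot:
    chrom: str
    position: int
    #: expected number of sequenced breaks at this site (Poisson mean)
    intensity: float


@dataclass(frozen=True)
class TrueDomain:
    chrom: str
    start: int
    end: int
    active: bool
    #: shared log2 expression baseline of the domain's genes
    baseline: float


@dataclass(frozen=True)
class TrueGene:
    gene_id: str
    chrom: str
    start: int
    end: int
    true_log_expression: float


@dataclass
class SimTruth:
    """Planted ground truth: hot spots, domains (tiling each chromosome
    between consecutive hot spots), and genes, each inside exactly one
    domain."""

    hotspots: list[Hotspot] = field(default_factory=list)
    true_domains: list[TrueDomain] = field(default_factory=list)
    genes: list[TrueGene] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "hotspots": [dataclasses.asdict(h) for h in self.hotspots],
                "true_domains": [dataclasses.asdict(d) for d in self.true_domains],
                "genes": [dataclasses.asdict(g) for g in self.genes],
            },
            indent=0,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        obj = json.loads(text)
        return cls(
            hotspots=[Hotspot(**h) for h in obj["hotspots"]],
            true_domains=[TrueDomain(**d) for d in obj["true_domains"]],
            genes=[TrueGene(**g) for g in obj["genes"]],
        )


@dataclass
class GenomeModel:
    chrom_lengths: dict[str, int]
    #: sorted Sau3A (GATC) site positions per chromosome
    sau3a_sites: dict[str, np.ndarray]
    #: optional per-chromosome sequence (sequence-backed mode)
    sequences: Optional[dict[str, str]] = None


def _geometric_sites(rng: np.random.Generator, length: int, mean: float) -> np.ndarray:
    """Site positions with geometric spacing (mean ``mean``), within [1, length)."""
    p = 1.0 / mean
    pos: list[np.ndarray] = []
    total = 0
    while total < length:
        draws = rng.geometric(p, size=max(64, int(length / mean) + 64))
        cum = np.cumsum(draws) + total
        pos.append(cum)
        total = int(cum[-1])
    sites = np.concatenate(pos)
    return sites[sites < length]


def simulate_genome(
    config: SimConfig, with_sequence: bool = False
) -> tuple[GenomeModel, SimTruth]:
    """Plant Sau3A sites, break hot spots, domains and genes.

    Hot-spot gaps are log-normal with the configured median; domains tile
    each chromosome between consecutive hot spots (terminal segments
    included).  A chromosome shorter than twice the spacing median gets
    no hot spots (with a warning) and becomes a single domain.  With
    ``with_sequence`` a random sequence is generated and GATC sites are
    taken from it instead of the point process.
    """
    rng = np.random.default_rng([_STREAM_GENOME, config.seed])
    sau3a: dict[str, np.ndarray] = {}
    sequences: dict[str, str] = {}
    truth = SimTruth()
    mu = math.log(config.hotspot_spacing_median)

    for chrom, length in config.chrom_lengths.items():
        if with_sequence:
            seq = "".join(rng.choice(list("ACGT"), size=length))
            sequences[chrom] = seq
            hits = []
            i = seq.find("GATC")
            while i != -1:
                hits.append(i)
                i = seq.find("GATC", i + 1)
            sau3a[chrom] = np.array(hits, dtype=np.int64)
        else:
            sau3a[chrom] = _geometric_sites(rng, length, config.sau3a_spacing_mean)

        if length < 2 * config.hotspot_spacing_median:
            logger.warning(
                "%s (%d bp) is shorter than twice the hot-spot spacing median; "
                "planting no hot spots on it",
                chrom,
                length,
            )
            positions = np.array([], dtype=np.int64)
        else:
            gaps: list[int] = []
            total = 0
            while total < length:
                g = int(round(rng.lognormal(mu, config.hotspot_spacing_logsd)))
                g = max(g, 1)
                total += g
                gaps.append(g)
            positions = np.cumsum(gaps)[:-1]
            positions = positions[(positions > 0) & (positions < length)]

        intensities = rng.gamma(4.0, config.reads_per_hotspot_mean / 4.0, size=len(positions))
        for pos, inten in zip(positions, intensities):
            truth.hotspots.append(Hotspot(chrom, int(pos), float(inten)))

        boundaries = [0, *positions.tolist(), length]
        for a, b in zip(boundaries, boundaries[1:]):
            if b <= a:
                continue
            active = bool(rng.random() < config.frac_active_domains)
            baseline = float(abs(rng.normal(0.0, config.domain_effect_sd))) if active else 0.0
            truth.true_domains.append(TrueDomain(chrom, int(a), int(b), active, baseline))
            n_genes = int(rng.poisson(config.genes_per_domain_mean))
            size = b - a
            if n_genes == 0 or size < 2 * n_genes:
                continue
            slot = size / n_genes
            for i in range(n_genes):
                s0 = a + i * slot
                glen = max(2, int(slot * rng.uniform(0.1, 0.6)))
                gstart = int(s0 + rng.uniform(0, slot - glen))
                truth.genes.append(
                    TrueGene(
                        gene_id=f"{chrom}_g{len(truth.genes):05d}",
                        chrom=chrom,
                        start=gstart,
                        end=gstart + glen,
                        true_log_expression=baseline,
                    )
                )

    genome = GenomeModel(
        chrom_lengths=dict(config.chrom_lengths),
        sau3a_sites=sau3a,
        sequences=sequences if with_sequence else None,
    )
    logger.info(
        "simulated genome: %d chromosomes, %d hot spots, %d domains, %d genes",
        len(config.chrom_lengths),
        len(truth.hotspots),
        len(truth.true_domains),
        len(truth.genes),
    )
    return genome, truth


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def simulate_raft_reads(
    genome: GenomeModel, truth: SimTruth, config: SimConfig
) -> tuple[list[SeqRecord], list[MappedRead]]:
    """Generate break-capture reads and their ground-truth alignments.

    Break positions are drawn per hot spot (Poisson counts with the hot
    spot's intensity, Gaussian jitter around its position; out-of-range
    draws are resampled) plus a uniform background.  Each break emits,
    independently per flank with probability ``side_capture_prob``, a
    fragment from the cut to the nearest GATC site on that side,
    truncated to ``read_max_len`` from the cut.  Fragments shorter than
    18 bp are still emitted — length filtering belongs to the pipeline.
    Truth alignments are 0-based half-open; strand encodes the cut side
    ('+' = cut at the left interval edge).
    """
    rng = np.random.default_rng([_STREAM_READS, config.seed])
    reads: list[SeqRecord] = []
    aligns: list[MappedRead] = []
    break_id = 0

    for chrom, length in genome.chrom_lengths.items():
        sites = genome.sau3a_sites[chrom]
        seq = genome.sequences.get(chrom) if genome.sequences else None

        cuts: list[int] = []
        for hs in truth.hotspots:
            if hs.chrom != chrom:
                continue
            for _ in range(int(rng.poisson(hs.intensity))):
                cut = int(round(hs.position + rng.normal(0.0, config.cut_jitter_sd)))
                while not 1 <= cut <= length - 1:  # outside chromosome: resample
                    cut = int(round(hs.position + rng.normal(0.0, config.cut_jitter_sd)))
                cuts.append(cut)
        n_bg = int(rng.poisson(config.background_break_rate * length))
        if n_bg:
            cuts.extend(int(c) for c in rng.integers(1, length, size=n_bg))

        for cut in cuts:
            bid = f"b{break_id:06d}"
            break_id += 1
            for side in ("left_flank", "right_flank"):
                if rng.random() >= config.side_capture_prob:
                    continue
                if side == "left_flank":
                    j = int(np.searchsorted(sites, cut, side="right")) - 1
                    # a site exactly at the cut leaves nothing on this side
                    boundary = int(sites[j]) if j >= 0 else 0
                    start = max(boundary, cut - config.read_max_len)
                    end = cut
                    cut_side, strand = "right", "-"
                else:
                    j = int(np.searchsorted(sites, cut, side="right"))
                    boundary = int(sites[j]) if j < len(sites) else length
                    start = cut
                    end = min(boundary, cut + config.read_max_len)
                    cut_side, strand = "left", "+"
                if end <= start:
                    continue
                rid = f"{bid}/{'L' if cut_side == 'right' else 'R'}"
                if seq is not None:
                    insert = seq[start:end]
                    if cut_side == "right":  # sequenced from the cut at the right edge
                        insert = str(Seq(insert).reverse_complement())
                else:
                    insert = _random_bases(rng, end - start)
                reads.append(
                    SeqRecord(
                        Seq(DSB_ADAPTOR + insert + SAU3A_ADAPTOR),
                        id=rid,
                        description=f"{chrom}:{start}-{end} cut_side={cut_side}",
                    )
                )
                aligns.append(
                    MappedRead(
                        chrom=chrom,
                        start=start,
                        end=end,
                        strand=strand,
                        cut_side=cut_side,
                        read_id=rid,
                    )
                )
    logger.info("simulated %d breaks yielding %d reads", break_id, len(reads))
    return reads, aligns


def simulate_expression(truth: SimTruth, config: SimConfig) -> pd.DataFrame:
    """Per-gene log2 expression: domain baseline + independent gene noise.

    Returns a table with columns gene_id/chrom/start/end/value.  An empty
    gene list yields an empty table with a warning.
    """
    rng = np.random.default_rng([_STREAM_EXPRESSION, config.seed])
    if not truth.genes:
        logger.warning("truth contains no genes; returning an empty expression table")
        return pd.DataFrame(columns=["gene_id", "chrom", "start", "end", "value"])
    noise = rng.normal(0.0, config.gene_noise_sd, size=len(truth.genes)) \
        if config.gene_noise_sd > 0 else np.zeros(len(truth.genes))
    return pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in truth.genes],
            "chrom": [g.chrom for g in truth.genes],
            "start": [g.start for g in truth.genes],
            "end": [g.end for g in truth.genes],
            "value": [g.true_log_expression + float(e) for g, e in zip(truth.genes, noise)],
        }
    )


def domains_from_truth(truth: SimTruth) -> list[ForumDomain]:
    """Planted domains as ForumDomain objects (for testing downstream stages
    against ground truth without running the calling pipeline)."""
    return [
        ForumDomain(d.chrom, d.start, d.end, bounded=True) for d in truth.true_domains
    ]


def write_reads_fasta(reads: list[SeqRecord], path: str | os.PathLike) -> None:
    from Bio import SeqIO

    SeqIO.write(reads, str(path), "fasta")


def write_truth_json(truth: SimTruth, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(truth.to_json())


def write_expression_tsv(expr: pd.DataFrame, path: str | os.PathLike) -> None:
    expr.to_csv(path, sep="\t", index=False)


def read_expression_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
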