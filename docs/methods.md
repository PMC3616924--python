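# Methods

## Scope and model

`forumdomains` re-implements the computational arm of genome-wide
blunt-end double-strand-break (DSB) mapping. The experimental construct
captures, at every blunt break, the DNA running from the cut to the
nearest downstream Sau3A restriction site (GATC); sequencing these
fragments ("forum-domain termini", FT) and mapping them gives a
genome-wide catalogue of break positions. Recurrently broken positions
("hot spots") appear as stacks of overlapping reads, and the intervals
between consecutive hot spots are the protected *forum domains*
(typically 50–250 kb, median ≈ 110 kb, range ≈ 1 kb–3 Mb). The package
covers read clean-up, FT calling, domain segmentation, density and
saturation profiles, a Monte-Carlo region-enrichment test, and
domain-level expression analysis including a circular-permutation test
of within-domain co-expression. Alignment itself is out of scope: the
pipeline consumes mapped intervals (BED) and the simulator emits
ground-truth alignments.

## Synthetic data generator

The generator is first-class, tested code; it defines the study
conditions under which everything else is validated.

* **Hot-spot spacing.** Inter-hot-spot gaps are log-normal with
  configurable median (default 110 kb, scaled down in tests) and log-sd
  1.1. The log-normal is chosen because the observed domain-size
  distribution is strongly right-skewed (1 kb to 3 Mb around a 110 kb
  median); log-sd 1.1 spans roughly that range at ±3 sd. A chromosome
  shorter than twice the spacing median receives no hot spots (with a
  warning) and becomes one domain.
* **Restriction sites.** Sau3A sites are a geometric point process with
  mean spacing 256 bp — the expectation for the 4-mer GATC in random
  sequence — rather than being derived from simulated sequence, which is
  faster at chromosome scale. A sequence-backed mode generates random
  sequence and takes real GATC positions from it, for tests that need
  base-level realism.
* **Breaks and fragments.** Each hot spot draws a Poisson number of
  breaks with a per-hot-spot gamma intensity (shape 4, mean
  `reads_per_hotspot_mean`); cut positions jitter around the hot spot
  (Gaussian, sd 15 bp by default, matching break clusters spread over a
  few tens of bp); a uniform background break rate adds isolated cuts.
  Each break emits up to two fragments, one per flank, independently
  retained with probability 0.5 (per-flank recovery is not reported for
  the real protocol; 0.5 is a stated default, not an inference). A
  fragment runs from the cut to the nearest GATC on its flank, truncated
  to `read_max_len` (300 bp) measured from the cut end, because
  sequencing starts from the ligated biotinylated end. A flank whose
  nearest GATC coincides with the cut emits nothing. Fragments shorter
  than 18 bp are still emitted — filtering is the pipeline's job, and
  the tests rely on that separation.
* **Sequencing depth.** The default of 20 expected reads per hot spot
  describes a library sequenced to saturation, which is what the
  original protocol demonstrates (the recovery curve plateaus between
  90% and 100% of reads); at much lower depth a visible fraction of hot
  spots falls below the two-read support threshold and the library is no
  longer saturated.
* **Expression.** ~30% of domains are active; an active domain draws a
  shared baseline |N(0, `domain_effect_sd`)| in log2 units (half-normal
  keeps log-expression non-negative; the data give no units, so the
  silent floor is 0 in log2(signal+1) space). Every gene adds
  independent N(0, `gene_noise_sd`) noise to its domain baseline. Genes
  are placed in non-overlapping slots inside their domain, so each gene
  lies in exactly one domain.

What the generator does **not** model: sequencing errors and 454
homopolymer artifacts, PCR duplicates, mappability/masking, copy-number
variation, distance-dependent expression correlation beyond the shared
domain baseline, and any correlation between break intensity and
transcription. Passing tests therefore demonstrate correctness of the
algorithms under the stated generative assumptions, not robustness to
those real-data complications.

## Pipeline conventions and numerical choices

* **Trimming.** A primer (or its reverse complement) is searched at each
  read end at offsets 0–5 bp; on a match the primer plus everything
  outside it is removed. Matching is exact by default
  (`max_mismatches=0`); the positional rule's mismatch tolerance is not
  documented for the original pipeline, so it is configurable. Reads
  shorter than 18 bp after trimming are removed.
* **Coordinates.** 0-based half-open everywhere in memory and in BED;
  GFF3 output is 1-based inclusive; WIG is fixedStep and 1-based. For a
  '+' alignment the break is the left interval edge, for '−' the right;
  the convention is configurable because it is a property of the
  upstream mapper.
* **FT calling.** Reads merge when their intervals share at least one
  base (`min_gap=0`, strict overlap; a positive `min_gap` also merges
  reads separated by at most that many bases). Strands merge together —
  the two flanks of one break face each other. FT with
  `read_count >= 2` (configurable) are flagged as hot spots; single-read
  FT are retained unflagged.
* **Segmentation.** Domains are the gaps *between* boundary FT
  (hot-spot-flagged by default), excluding the FT intervals themselves,
  so bounded domains + FT + terminal segments exactly tile each
  chromosome. Terminal segments are unbounded and excluded from size
  statistics, which would otherwise be biased by chromosome ends.
  Gene-to-domain assignment is by gene midpoint, so a
  boundary-straddling gene lands in exactly one domain.
* **Density and saturation.** An FT is counted in a window when its
  midpoint falls in it (no double counting across overlapping windows;
  a step-sized tiling conserves the total). Saturation subsamples reads
  without replacement, independently per schedule point (substream
  seeds derived from the master seed); an FT counts as recovered when
  any subsample FT overlaps it. Because subsamples are independent, the
  empirical curve is monotone only in expectation; tests compare
  adjacent points against their Monte-Carlo standard errors.
* **Enrichment.** Each null replicate re-places the chromosome's FT
  uniformly (observed lengths kept, overlaps permitted — the
  randomization preserves "the same length limits and numbers", nothing
  more) and counts overlaps with the query region; p_mc carries a +1
  pseudocount so it is never zero. The analytic companion is the
  binomial upper tail under a point-FT approximation, evaluated through
  the log survival function; it supplies tails (p < 1e-7) beyond the
  resolution of any practical replicate count. PRNG: numpy's PCG64,
  seeded and logged.
* **Expression.** Per-gene value = median of exon signals
  (mean-of-middles on even counts), then log2(x+1) (configurable).
  Domain median over its genes; a domain is *active* when its median
  exceeds the arithmetic mean of per-domain medians on its chromosome
  (gene-bearing domains only; gene-less domains are classed low/silent
  and excluded from the average).
* **Coordination test.** D = mean over domains with ≥2 genes of the
  within-domain sample variance of gene values (variance is computed
  centered for stability; mean absolute deviation from the domain
  median is available as an alternative statistic, since the original
  dispersion statistic is not published in the available text). The null
  rotates each chromosome's position-ordered gene-value vector by an
  independent uniform offset in gene-rank space, keeping the
  gene-to-domain pattern fixed; rotation preserves autocorrelation while
  breaking alignment. One-sided p = (1 + #{D_null ≤ D_obs})/(1 + reps).
  An exact mode enumerates all offsets on a single chromosome. Note that
  a single chromosome admits only n distinct rotations, so very small
  p-values require several chromosomes rotated jointly — the
  genome-wide setting.

## Problem sizes used in tests

Tests and the acceptance script run on scaled-down genomes chosen so the
statistics they check are well-resolved: chromosomes of 0.4–4 Mb with
hot-spot spacing medians of 15–50 kb (≈ 40–160 hot spots each),
libraries of ~200–3,700 reads, 200 null datasets for calibration of the
coordination test, 1e5 replicates for Monte-Carlo/analytic agreement,
and 20 seeds for hot-spot recovery. The full suite runs in well under a
minute.

## Known limitations

* The analytic enrichment tail treats FT as points; for FT lengths
  comparable to the region it is only an approximation (the Monte-Carlo
  value is exact up to sampling error and is always reported alongside).
* Closely spaced breaks with one-sided fragment dropout can split a hot
  spot into two adjacent flagged FT, creating occasional sub-read-length
  domains; this shifts the called domain-size median a few percent below
  the planted spacing median.
* Multi-mapping reads are taken at face value; the original study mapped
  against a masked genome and its multi-hit handling is not described.
* The exact-enumeration coordination test does not extend to multiple
  chromosomes.
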