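# forumdomains

Genome-wide mapping of blunt-ended DNA double-strand breaks (DSBs) and
the chromosomal domains they delimit.

Spontaneous blunt DSBs are not scattered uniformly along human
chromosomes: they cluster at hot spots that fence off protected
50–250 kb *forum domains*. Experimentally, each break is captured as a
short fragment — a *forum-domain terminus* (FT) — running from the cut
to the nearest Sau3A (GATC) restriction site, typically 50–300 bp.
`forumdomains` implements the computational pipeline that turns these
reads into biology, for genomicists studying chromosome fragility and
domain-level gene regulation:

* **read clean-up** — positional primer trimming (primer within 5 bp of
  a read end) and the ≥18 bp length filter;
* **FT calling** — maximal unions of overlapping mapped reads, with
  hot-spot flags for FT supported by ≥2 reads;
* **domain segmentation** — forum domains as the gaps between
  consecutive hot spots, with size statistics and gene content;
* **profiles** — FT density in sliding windows (500 kb window / 100 kb
  step) and read-subsampling saturation curves;
* **enrichment** — a Monte-Carlo test for excess FT in a query region
  (each of `reps` replicates re-places the chromosome's FT uniformly,
  keeping their number and lengths), with an analytic binomial tail
  P(X ≥ k), X ~ Bin(n, region/chrom), for probabilities beyond
  Monte-Carlo resolution;
* **expression** — per-domain median expression, active/silent
  classification against the chromosome average, and a
  circular-permutation test of within-domain co-expression: the
  statistic D is the mean within-domain variance of gene expression,
  and the null rotates each chromosome's position-ordered gene values
  by a random offset, giving one-sided
  p = (1 + #{D_null ≤ D_obs}) / (1 + reps);
* **a synthetic-data generator** — toy genomes with planted hot spots
  (log-normal spacing), restriction-bounded reads with ground-truth
  alignments, and domain-coordinated expression (~30% active domains),
  so every stage is testable without downloads.

## Worked example

Run the whole pipeline on a simulated 1 Mb chromosome with ~20 kb
hot-spot spacing:

```sh
$ printf 'chrom_lengths:\n  chr1: 1000000\nhotspot_spacing_median: 20000\nseed: 7\n' > toy.yaml
$ forumdomains run --config toy.yaml --outdir out
run: 176 reads, 22 FT, 19 bounded domains -> out
```

`out/` now holds the reads (`reads.fasta`), their ground-truth
alignments (`truth_alignments.bed`), the called FT (`ft.bed`,
`ft.gff3`), the segmented domains (`domains.bed`), a density track
(`density.wig`), a saturation curve (`saturation.tsv`), per-domain
expression (`domain_expression.tsv`), and the effective configuration.
The first called FT:

```
chr1	15683	16182	chr1:15683-16182	17	.
```

is a 499 bp terminus supported by 17 overlapping reads — a break hot
spot. Test whether the first 100 kb carries more FT than chance:

```sh
$ forumdomains enrich --ft out/ft.gff3 --region chr1:0-100000 \
      --chrom-sizes out/chrom.sizes --reps 10000 --out enrich.json
enrich: observed=4, p_mc=0.177, p_analytic=0.172
```

Four FT in 10% of the chromosome is unremarkable (p ≈ 0.18 by both the
Monte-Carlo null and the binomial tail). Expression inside domains,
however, is strongly coordinated in this simulation:

```sh
$ forumdomains coexpress --expr out/expression.tsv \
      --domains out/domains.bed --reps 10000 --out coex.json
coexpress: D=0.1636, p=0.0132 over 19 multi-gene domains
```

The within-domain variance (D = 0.16 log2²) is smaller than in 98.7% of
random circular shifts: genes in the same domain rise and fall
together. (With a single 1 Mb chromosome only ~100 distinct rotations
exist; genome-wide runs over several chromosomes resolve far smaller
p-values.)

## Layout

```
src/forumdomains/
  simulate.py      synthetic genomes, reads, expression (+ ground truth)
  reads.py         trimming, length filter, BED alignment IO
  ft.py            FT calling, hot-spot flags, BED/GFF3 export
  segmentation.py  forum domains, size stats, gene content
  profiles.py      density tracks (WIG), saturation curves
  enrichment.py    Monte-Carlo + analytic region enrichment
  expression.py    domain expression, activity classes, circular-shift test
  cli.py           `forumdomains` subcommands and the `run` pipeline
docs/methods.md    model, parameters, numerical choices, limitations
```
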