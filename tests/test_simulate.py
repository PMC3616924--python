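"""The generator's planted truth must respect its own stated geometry and
statistics: deterministic under a seed, log-normal hot-spot spacing with the
configured median, restriction-bounded fragments, domain-coordinated
expression."""

import logging

import numpy as np
import pytest

from forumdomains import SimConfig, simulate_expression, simulate_genome, simulate_raft_reads
from forumdomains.simulate import GenomeModel, Hotspot, SimTruth, TrueDomain


def test_identical_seed_gives_byte_identical_truth_and_reads():
    cfg = SimConfig(chrom_lengths={"c": 500_000}, hotspot_spacing_median=20_000, seed=42)
    out = []
    for _ in range(2):
        genome, truth = simulate_genome(cfg)
        reads, aligns = simulate_raft_reads(genome, truth, cfg)
        expr = simulate_expression(truth, cfg)
        out.append(
            (
                truth.to_json(),
                [(r.id, str(r.seq)) for r in reads],
                [(a.chrom, a.start, a.end, a.cut_side) for a in aligns],
                expr.to_csv(),
            )
        )
    assert out[0] == out[1]


def test_truth_json_round_trip():
    cfg = SimConfig(chrom_lengths={"c": 300_000}, hotspot_spacing_median=20_000, seed=1)
    _, truth = simulate_genome(cfg)
    assert SimTruth.from_json(truth.to_json()).to_json() == truth.to_json()


def test_hotspot_count_matches_renewal_oracle():
    """Mean number of hot spots on a 1 Mb chromosome equals the renewal count
    of the same log-normal gap process, simulated independently."""
    n_rep = 200
    median, logsd, length = 100_000, 0.25, 1_000_000
    counts = []
    for seed in range(n_rep):
        cfg = SimConfig(
            chrom_lengths={"c": length},
            hotspot_spacing_median=median,
            hotspot_spacing_logsd=logsd,
            seed=seed,
        )
        _, truth = simulate_genome(cfg)
        counts.append(len(truth.hotspots))

    # independent renewal oracle on the same gap distribution
    rng = np.random.default_rng(987654)
    oracle = []
    for _ in range(n_rep):
        total, k = 0.0, 0
        while True:
            total += rng.lognormal(np.log(median), logsd)
            if total >= length:
                break
            k += 1
        oracle.append(k)
    assert abs(np.mean(counts) - np.mean(oracle)) < 1.0
    # with a nearly symmetric gap distribution this is ~9-10 per Mb
    assert 8.0 <= np.mean(counts) <= 10.5


def test_spacing_median_recovered_from_pooled_gaps():
    gaps = []
    seed = 0
    while len(gaps) < 500:
        cfg = SimConfig(
            chrom_lengths={"c": 3_000_000}, hotspot_spacing_median=20_000, seed=seed
        )
        _, truth = simulate_genome(cfg)
        pos = [h.position for h in truth.hotspots]
        gaps.extend(np.diff(pos))
        seed += 1
    rel_err = abs(np.median(gaps) - 20_000) / 20_000
    assert rel_err < 0.10


def test_short_chromosome_gets_no_hotspots_and_warns(caplog):
    cfg = SimConfig(
        chrom_lengths={"tiny": 10_000}, hotspot_spacing_median=20_000, seed=0
    )
    with caplog.at_level(logging.WARNING):
        _, truth = simulate_genome(cfg)
    assert truth.hotspots == []
    assert len(truth.true_domains) == 1
    assert any("no hot spots" in r.message for r in caplog.records)


def test_domains_tile_chromosome_and_genes_lie_inside_one_domain():
    cfg = SimConfig(chrom_lengths={"c": 1_000_000}, hotspot_spacing_median=15_000, seed=5)
    _, truth = simulate_genome(cfg)
    doms = sorted(truth.true_domains, key=lambda d: d.start)
    assert doms[0].start == 0 and doms[-1].end == 1_000_000
    for a, b in zip(doms, doms[1:]):
        assert a.end == b.start
    for g in truth.genes:
        containing = [d for d in doms if d.start <= g.start and g.end <= d.end]
        assert len(containing) == 1


def test_zero_active_fraction_means_all_domains_silent():
    cfg = SimConfig(
        chrom_lengths={"c": 1_000_000},
        hotspot_spacing_median=15_000,
        frac_active_domains=0.0,
        seed=2,
    )
    _, truth = simulate_genome(cfg)
    assert truth.true_domains and all(not d.active for d in truth.true_domains)
    assert all(d.baseline == 0.0 for d in truth.true_domains)


def test_active_fraction_recovered_over_seeds():
    """Planted 30% activity is recovered over >=500 pooled domains within the
    binomial 99% interval."""
    active = total = 0
    for seed in range(30):
        cfg = SimConfig(
            chrom_lengths={"c": 1_000_000}, hotspot_spacing_median=15_000, seed=seed
        )
        _, truth = simulate_genome(cfg)
        total += len(truth.true_domains)
        active += sum(d.active for d in truth.true_domains)
    assert total >= 500
    phat = active / total
    half = 2.58 * np.sqrt(0.3 * 0.7 / total)
    assert abs(phat - 0.30) < half + 0.01


def _toy_genome(sites, length=20_000):
    return GenomeModel(
        chrom_lengths={"c": length}, sau3a_sites={"c": np.array(sites, dtype=np.int64)}
    )


def _toy_truth(cut, intensity=50.0, length=20_000):
    return SimTruth(
        hotspots=[Hotspot("c", cut, intensity)],
        true_domains=[TrueDomain("c", 0, length, False, 0.0)],
        genes=[],
    )


def _forced_cfg(**kw):
    base = dict(
        chrom_lengths={"c": 20_000},
        hotspot_spacing_median=1_000,
        cut_jitter_sd=1e-9,
        side_capture_prob=1.0,
        background_break_rate=0.0,
        seed=0,
    )
    base.update(kw)
    return SimConfig(**base)


def test_fragment_geometry_forced_by_construct():
    """A cut at 10,000 with flanking GATC at 9,880 and 10,140 must yield
    fragments [9880,10000) (cut on the right end) and [10000,10140)."""
    cfg = _forced_cfg()
    genome = _toy_genome([9_880, 10_140])
    _, aligns = simulate_raft_reads(genome, _toy_truth(10_000), cfg)
    got = {(a.start, a.end, a.cut_side) for a in aligns}
    assert got == {(9_880, 10_000, "right"), (10_000, 10_140, "left")}


def test_fragment_truncated_to_read_max_len_from_cut():
    cfg = _forced_cfg(read_max_len=300)
    genome = _toy_genome([9_600, 10_400])  # 400 bp from the cut on both sides
    _, aligns = simulate_raft_reads(genome, _toy_truth(10_000), cfg)
    got = {(a.start, a.end, a.cut_side) for a in aligns}
    assert got == {(9_700, 10_000, "right"), (10_000, 10_300, "left")}


def test_alignment_ends_are_cut_or_sau3a_bounded(small_sim):
    cfg, genome, _, _, aligns = small_sim[:5]
    sites = set(genome.sau3a_sites["chr1"].tolist())
    for a in aligns:
        truncated = (a.end - a.start) == cfg.read_max_len
        if a.cut_side == "left":  # cut at start, Sau3A (or chrom end) at end
            assert truncated or a.end in sites or a.end == cfg.chrom_lengths["chr1"]
        else:
            assert truncated or a.start in sites or a.start == 0


def test_background_zero_keeps_cuts_near_hotspot():
    cfg = _forced_cfg(cut_jitter_sd=10.0)
    genome = _toy_genome(list(range(200, 20_000, 250)))
    _, aligns = simulate_raft_reads(genome, _toy_truth(10_000, intensity=80.0), cfg)
    assert aligns
    for a in aligns:
        assert abs(a.cut_position - 10_000) <= 4 * cfg.cut_jitter_sd


def test_sequence_backed_mode_puts_gatc_at_fragment_boundaries():
    cfg = SimConfig(
        chrom_lengths={"c": 60_000},
        hotspot_spacing_median=8_000,
        side_capture_prob=1.0,
        seed=4,
    )
    genome, truth = simulate_genome(cfg, with_sequence=True)
    seq = genome.sequences["c"]
    for s in genome.sau3a_sites["c"]:
        assert seq[s : s + 4] == "GATC"
    _, aligns = simulate_raft_reads(genome, truth, cfg)
    for a in aligns[:50]:
        if a.cut_side == "left" and a.end - a.start < cfg.read_max_len \
                and a.end < len(seq) - 4:
            assert seq[a.end : a.end + 4] == "GATC"


def test_zero_gene_noise_gives_identical_values_within_domain():
    cfg = SimConfig(
        chrom_lengths={"c": 500_000},
        hotspot_spacing_median=15_000,
        gene_noise_sd=1e-12,
        seed=9,
    )
    _, truth = simulate_genome(cfg)
    expr = simulate_expression(truth, cfg)
    doms = sorted(truth.true_domains, key=lambda d: d.start)
    mids = (expr["start"] + expr["end"]) // 2
    for d in doms:
        vals = expr.loc[(mids >= d.start) & (mids < d.end), "value"]
        if len(vals) > 1:
            assert vals.max() - vals.min() < 1e-6


def test_empty_gene_list_yields_empty_expression_table(caplog):
    truth = SimTruth(hotspots=[], true_domains=[TrueDomain("c", 0, 1000, False, 0.0)])
    cfg = SimConfig(chrom_lengths={"c": 1_000}, hotspot_spacing_median=100, seed=0)
    with caplog.at_level(logging.WARNING):
        expr = simulate_expression(truth, cfg)
    assert expr.empty


@pytest.mark.parametrize(
    "kw",
    [
        {"chrom_lengths": {}},
        {"chrom_lengths": {"c": 0}},
        {"frac_active_domains": 1.5},
        {"read_min_len": 300, "read_max_len": 300},
        {"hotspot_spacing_median": 0},
    ],
)
def test_invalid_config_rejected(kw):
    base = dict(chrom_lengths={"c": 10_000}, hotspot_spacing_median=1_000)
    base.update(kw)
    with pytest.raises(ValueError):
        SimConfig(**base)
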