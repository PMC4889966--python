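"""Simulator: determinism, genome composition, CNV sampling law, and
truth-table concordance of both read arms."""

import gzip

import numpy as np
import pytest
from Bio import SeqIO

from smashcn.binning import count_maps, make_bins, mappability_mask
from smashcn.genome import Genome
from smashcn.index import build_index
from smashcn.mapping import LKRule, map_read_pair, map_wgs_read
from smashcn.simulator import (
    BiasSpec,
    FragmentSpec,
    GenomeSpec,
    SimulationConfig,
    SmashSpec,
    TruthTable,
    WgsSpec,
    simulate_genome,
    simulate_smash_reads,
    simulate_wgs_reads,
    spike_cnvs,
    systematic_field,
    write_fastq_pairs,
)


class TestSimulateGenome:
    def test_seeded_determinism_byte_identical(self, tmp_path):
        spec = GenomeSpec(chromosomes=(("chr1", 50_000),))
        cfg = SimulationConfig(seed=7, genome=spec)
        g1, _ = simulate_genome(spec, 7)
        g2, _ = simulate_genome(spec, 7)
        assert g1.sequences == g2.sequences
        w = spike_cnvs(g1, [], "male")
        p1, _ = simulate_smash_reads(g1, w, cfg, 50)
        p2, _ = simulate_smash_reads(g2, w, cfg, 50)
        f1a, f1b = tmp_path / "a1.fq.gz", tmp_path / "a2.fq.gz"
        f2a, f2b = tmp_path / "b1.fq.gz", tmp_path / "b2.fq.gz"
        write_fastq_pairs(p1, str(f1a), str(f1b))
        write_fastq_pairs(p2, str(f2a), str(f2b))
        assert gzip.open(f1a).read() == gzip.open(f2a).read()
        assert gzip.open(f1b).read() == gzip.open(f2b).read()

    def test_constant_gc_field_realized(self):
        spec = GenomeSpec(chromosomes=(("chr1", 1_000_000),), gc_amplitude=0.0)
        g, fields = simulate_genome(spec, 3)
        seq = g.sequences["chr1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.5) < 0.01
        assert np.allclose(fields["chr1"], 0.5)

    def test_gc_drift_present_by_default(self):
        spec = GenomeSpec(chromosomes=(("chr1", 400_000),))
        _, fields = simulate_genome(spec, 4)
        assert np.ptp(fields["chr1"]) > 0.05

    def test_planted_duplication_kills_mappability(self):
        spec = GenomeSpec(
            chromosomes=(("chr1", 60_000),),
            duplications=(("chr1", 5000, 1000, "chr1", 40_000),),
        )
        g, _ = simulate_genome(spec, 5)
        idx = build_index(g)
        mask = mappability_mask(g, idx, k=50)["chr1"]
        assert mask[5000 : 6000 - 49].sum() == 0

    def test_invalid_length_rejected(self):
        with pytest.raises(ValueError):
            simulate_genome(GenomeSpec(chromosomes=(("chr1", 0),)), 1)


@pytest.fixture(scope="module")
def male_genome():
    g, _ = simulate_genome(
        GenomeSpec(chromosomes=(("chr1", 200_000), ("chrX", 100_000))), 6
    )
    return g


class TestSpikeCnvs:
    def test_baseline_weights_male(self, male_genome):
        w = spike_cnvs(male_genome, [], "male")
        assert (w["chr1"] == 2.0).all() and (w["chrX"] == 1.0).all()

    def test_female_x(self, male_genome):
        w = spike_cnvs(male_genome, [], "female")
        assert (w["chrX"] == 2.0).all()

    def test_zero_copy_region_yields_no_reads(self, male_genome):
        cfg = SimulationConfig(seed=8)
        cnvs = [("chr1", 50_000, 80_000, 0)]
        w = spike_cnvs(male_genome, cnvs, "male")
        pairs, truth = simulate_smash_reads(male_genome, w, cfg, 300)
        frs = truth.fragments
        inside = frs[(frs.chrom == "chr1") & (frs.start >= 50_000) & (frs.start < 80_000)]
        assert len(inside) == 0

    def test_overlapping_cnvs_rejected(self, male_genome):
        with pytest.raises(ValueError, match="overlap"):
            spike_cnvs(male_genome, [("chr1", 0, 1000, 3), ("chr1", 500, 2000, 1)], "male")

    def test_fragment_density_proportional_to_copy_number(self, male_genome):
        """Sampled fragment density tracks copy number within 10% at high
        depth."""
        cfg = SimulationConfig(seed=9, bias=BiasSpec(gc_coeff=0.0, systematic_sd=0.0))
        cnvs = [("chr1", 40_000, 90_000, 6)]
        w = spike_cnvs(male_genome, cnvs, "male")
        _, truth = simulate_smash_reads(male_genome, w, cfg, 4000)
        frs = truth.fragments[truth.fragments.chrom == "chr1"]
        amp = ((frs.start >= 40_000) & (frs.start < 90_000)).sum() / 50_000
        rest = ((frs.start < 40_000) | (frs.start >= 90_000)).sum() / 150_000
        assert amp / rest == pytest.approx(3.0, rel=0.10)


@pytest.fixture(scope="module")
def smash_setup():
    cfg = SimulationConfig(seed=10, genome=GenomeSpec(chromosomes=(("chr1", 400_000),)))
    cfg.smash.error_rate = 0.0
    cfg.smash.duplicate_rate = 0.0
    g, _ = simulate_genome(cfg.genome, cfg.seed)
    w = spike_cnvs(g, [], "male")
    pairs, truth = simulate_smash_reads(g, w, cfg, 500)
    return cfg, g, build_index(g), pairs, truth


class TestSmashReads:
    def test_chimera_lengths_within_selection_window(self, smash_setup):
        cfg, g, idx, pairs, truth = smash_setup
        totals = truth.fragments.groupby("molecule")["length"].sum()
        assert (totals >= cfg.smash.chimera_min).all()
        assert (totals <= cfg.smash.chimera_max).all()

    def test_fragment_lengths_truncated_normal(self, smash_setup):
        cfg, g, idx, pairs, truth = smash_setup
        lens = truth.fragments["length"]
        assert lens.min() >= 20 and lens.max() <= 150
        assert abs(lens.mean() - 45) < 3

    def test_mean_countable_maps_at_least_four(self, smash_setup):
        cfg, g, idx, pairs, truth = smash_setup
        total = sum(len(map_read_pair(r1, r2, idx, LKRule(20, 4))) for _, r1, r2 in pairs)
        assert total / len(pairs) >= 4.0

    def test_truth_fragments_recovered_by_maps(self, smash_setup):
        """≥95% of truth fragments with ≥24 bp inside a read are recovered
        by a kept map at the true locus (error-free run).

        The proximity collapse is disabled here (min_separation=0): on a
        single small chromosome, distinct fragments of one molecule often
        fall within 10 kb by chance, which is a counting policy rather
        than a recovery failure.
        """
        cfg, g, idx, pairs, truth = smash_setup
        rl = cfg.smash.read_len
        by_mol = dict(tuple(truth.fragments.groupby("molecule")))
        found = total = 0
        for rid, r1, r2 in pairs[:200]:
            mol = int(rid[2:9])
            frs = by_mol[mol]
            chim_len = frs["length"].sum()
            maps = map_read_pair(r1, r2, idx, LKRule(20, 4), min_separation=0)
            for f in frs.itertuples():
                off, ln = f.chimera_offset, f.length
                in_r1 = min(off + ln, rl) - off
                in_r2 = (off + ln) - max(off, chim_len - rl)
                if max(in_r1, in_r2) < 24 or ln < 24:
                    continue
                total += 1
                found += any(
                    m.chromosome == f.chrom
                    and m.position >= f.start - 3
                    and m.position + m.length <= f.start + f.length + 3
                    for m in maps
                )
        assert total > 300
        assert found / total >= 0.95

    def test_duplicate_multiplicity_consistent(self):
        cfg = SimulationConfig(seed=11, genome=GenomeSpec(chromosomes=(("chr1", 200_000),)))
        cfg.smash.duplicate_rate = 0.3
        g, _ = simulate_genome(cfg.genome, cfg.seed)
        w = spike_cnvs(g, [], "male")
        pairs, truth = simulate_smash_reads(g, w, cfg, 1000)
        assert len(pairs) == 1000
        assert truth.multiplicity().sum() == 1000
        assert truth.pairs["is_duplicate"].sum() == 1000 - truth.n_distinct_molecules


class TestWgsReads:
    def test_error_free_reads_map_to_true_position(self):
        cfg = SimulationConfig(seed=12, genome=GenomeSpec(chromosomes=(("chr1", 300_000),)))
        cfg.wgs.error_rate = 0.0
        cfg.wgs.duplicate_rate = 0.0
        g, _ = simulate_genome(cfg.genome, cfg.seed)
        idx = build_index(g)
        w = spike_cnvs(g, [], "male")
        pairs, truth = simulate_wgs_reads(g, w, cfg, 400)
        by_mol = truth.fragments.set_index("molecule")
        ok = 0
        for rid, r1, _r2 in pairs:
            mol = int(rid[2:9])
            m = map_wgs_read(r1, idx, clip_len=76)
            ok += m is not None and m.position == by_mol.loc[mol, "start"]
        assert ok / len(pairs) > 0.99

    def test_insert_lengths_in_window(self):
        cfg = SimulationConfig(seed=13, genome=GenomeSpec(chromosomes=(("chr1", 200_000),)))
        g, _ = simulate_genome(cfg.genome, cfg.seed)
        w = spike_cnvs(g, [], "male")
        _, truth = simulate_wgs_reads(g, w, cfg, 300)
        lens = truth.fragments["length"]
        assert lens.between(cfg.wgs.insert_min, cfg.wgs.insert_max).all()


def test_fastq_output_is_standard(tmp_path):
    cfg = SimulationConfig(seed=14, genome=GenomeSpec(chromosomes=(("chr1", 100_000),)))
    g, _ = simulate_genome(cfg.genome, cfg.seed)
    w = spike_cnvs(g, [], "male")
    pairs, _ = simulate_smash_reads(g, w, cfg, 20)
    p1, p2 = tmp_path / "r1.fastq", tmp_path / "r2.fastq"
    write_fastq_pairs(pairs, str(p1), str(p2))
    recs1 = list(SeqIO.parse(str(p1), "fastq"))
    recs2 = list(SeqIO.parse(str(p2), "fastq"))
    assert len(recs1) == len(recs2) == 20
    assert all(len(r.seq) == cfg.smash.read_len for r in recs1)


def test_systematic_field_shared_within_batch():
    g, _ = simulate_genome(GenomeSpec(chromosomes=(("chr1", 100_000),)), 15)
    a = systematic_field(g, BiasSpec(batch_seed=5))
    b = systematic_field(g, BiasSpec(batch_seed=5))
    c = systematic_field(g, BiasSpec(batch_seed=6))
    assert np.array_equal(a["chr1"], b["chr1"])
    assert not np.array_equal(a["chr1"], c["chr1"])
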