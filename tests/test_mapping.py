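"""L:K filtering, proximity collapse, duplicate removal and the WGS arm."""

import itertools

import numpy as np
import pytest

from smashcn.genome import Genome, revcomp
from smashcn.index import build_index
from smashcn.mapping import (
    LKRule,
    MapRecord,
    dedup_pairs,
    dedup_wgs_maps,
    lk_filter,
    map_read_pair,
    map_wgs_read,
    pair_signature,
    proximity_filter,
)
from smashcn.simulator import GenomeSpec, SimulationConfig, simulate_genome, simulate_smash_reads, spike_cnvs
from smashcn.pipeline import map_smash_pairs

from conftest import brute_count, random_seq


def mk(chrom, pos, length=25, strand="+", rid="p"):
    return MapRecord(chromosome=chrom, position=pos, strand=strand, length=length, read_pair_id=rid)


class TestLKRule:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            LKRule(4, 4)
        with pytest.raises(ValueError):
            LKRule(20, -1)
        with pytest.raises(ValueError):
            LKRule(20, 4, mode="mystery")

    def test_unique_planted_fragment_kept(self, index_100k, genome_100k):
        read = genome_100k.sequences["chr1"][30_000:30_030]
        mams = index_100k.find_mams(read, 20)
        kept = lk_filter(mams, LKRule(20, 4), index_100k, read)
        assert len(kept) == 1 and kept[0].position == 30_000

    def test_short_mam_dropped_regardless_of_uniqueness(self, index_100k, genome_100k):
        read = genome_100k.sequences["chr1"][30_000:30_019]
        mams = index_100k.find_mams(read, 15)
        assert mams and mams[0].length == 19
        assert lk_filter(mams, LKRule(20, 4), index_100k, read) == []

    def test_trim_check_matches_brute_force_counts(self):
        """A MAM unique only through a near-duplicate junction is dropped
        when its K-trims are non-unique, exactly as brute-force counting
        predicts."""
        core = random_seq(60, 7)
        # two near-copies differing at one base flanking distinct contexts
        left = random_seq(2000, 8)
        right = random_seq(2000, 9)
        variant = core[:30] + ("A" if core[30] != "A" else "C") + core[31:]
        genome = Genome({"chr1": left + core + right + variant})
        idx = build_index(genome)
        read = core
        mams = idx.find_mams(read, 20)
        for rule in (LKRule(20, 0), LKRule(20, 4), LKRule(20, 8)):
            kept = lk_filter(mams, rule, idx, read)
            for m in mams:
                s, e = m.query_start, m.query_start + m.length
                if m.length < rule.L:
                    expect = False
                elif rule.K == 0:
                    expect = True
                else:
                    expect = (
                        brute_count(read[s + rule.K : e], genome) == 1
                        and brute_count(read[s : e - rule.K], genome) == 1
                    )
                assert any(k.query_start == s for k in kept) == expect

    def test_either_mode_is_no_stricter_than_both(self, index_100k, genome_100k):
        seq = genome_100k.sequences["chr1"]
        read = seq[10_000:10_040] + seq[50_000:50_040]
        mams = index_100k.find_mams(read, 20)
        both = lk_filter(mams, LKRule(20, 8, "both"), index_100k, read)
        either = lk_filter(mams, LKRule(20, 8, "either"), index_100k, read)
        assert {m.query_start for m in both} <= {m.query_start for m in either}

    def test_k_monotonicity_on_simulated_reads(self, sim_bundle):
        """Countable maps under 20:8 ⊆ 20:4 ⊆ 20:0 for every read."""
        idx = sim_bundle.index
        subset = sim_bundle.smash_pairs[:150]
        for rid, r1, r2 in subset:
            per_rule = {}
            for K in (0, 4, 8):
                mams = idx.find_mams(r1, 20)
                kept = lk_filter(mams, LKRule(20, K), idx, r1)
                per_rule[K] = {(m.position, m.length) for m in kept}
            assert per_rule[8] <= per_rule[4] <= per_rule[0]


class TestProximityFilter:
    def test_different_chromosomes_both_kept(self):
        maps = [mk("chr1", 100), mk("chr2", 200)]
        assert len(proximity_filter(maps)) == 2

    def test_close_pair_reduced_to_one(self):
        # read spanning an indel: two maps 500 bp apart must not double count
        maps = [mk("chr1", 1000, length=30), mk("chr1", 1500, length=22)]
        out = proximity_filter(maps)
        assert len(out) == 1 and out[0].length == 30  # longest kept

    def test_tie_broken_leftmost(self):
        maps = [mk("chr1", 1000, length=25), mk("chr1", 1500, length=25)]
        out = proximity_filter(maps)
        assert out[0].position == 1000

    def test_three_map_cluster_all_orderings(self):
        base = [mk("chr1", 0, 25), mk("chr1", 5000, 30), mk("chr1", 20_000, 25)]
        for perm in itertools.permutations(base):
            out = proximity_filter(list(perm))
            assert len(out) == 2
            positions = sorted(m.position for m in out)
            assert positions[1] - positions[0] >= 10_000
            assert 20_000 in positions  # far map always survives
            assert 5000 in positions  # longest of the close cluster

    def test_result_has_no_close_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            maps = [mk("chr1", int(p), int(l)) for p, l in
                    zip(rng.integers(0, 60_000, 8), rng.integers(20, 40, 8))]
            out = proximity_filter(maps)
            pos = sorted(m.position for m in out)
            assert all(b - a >= 10_000 for a, b in zip(pos, pos[1:]))


class TestDedup:
    def test_identical_pairs_collapse(self):
        maps = [mk("chr1", 100), mk("chr2", 5000)]
        pairs = [("a", list(maps)), ("b", list(maps))]
        assert [rid for rid, _ in dedup_pairs(pairs)] == ["a"]

    def test_partially_shared_pairs_retained(self):
        pairs = [
            ("a", [mk("chr1", 100), mk("chr2", 5000)]),
            ("b", [mk("chr1", 100), mk("chr2", 9000)]),
        ]
        assert len(dedup_pairs(pairs)) == 2

    def test_signature_ignores_map_order(self):
        m1, m2 = mk("chr1", 100), mk("chr2", 5000)
        assert pair_signature([m1, m2]) == pair_signature([m2, m1])

    def test_empty_pairs_dropped(self):
        assert dedup_pairs([("a", [])]) == []

    def test_dedup_is_idempotent(self, sim_bundle):
        pairs = [(m.read_pair_id, [m]) for m in sim_bundle.smash_maps[:500]]
        once = dedup_pairs(pairs)
        assert dedup_pairs(once) == once

    def test_duplicate_rate_recovery_matches_truth(self):
        """With 20% PCR duplicates and error-free reads, dedup retains
        exactly the simulator's distinct-molecule count."""
        cfg = SimulationConfig(seed=5, genome=GenomeSpec(chromosomes=(("chr1", 400_000),)))
        cfg.smash.duplicate_rate = 0.2
        cfg.smash.error_rate = 0.0
        genome, _ = simulate_genome(cfg.genome, cfg.seed)
        idx = build_index(genome)
        weights = spike_cnvs(genome, [], "male")
        pairs, truth = simulate_smash_reads(genome, weights, cfg, 800)
        assert truth.pairs["is_duplicate"].sum() > 100
        _maps, stats = map_smash_pairs(pairs, idx, LKRule(20, 4), 10_000)
        assert stats["pairs_retained"] == truth.n_distinct_molecules


class TestWgsArm:
    def test_unique_locus_maps_to_true_position(self, index_100k, genome_100k):
        read = genome_100k.sequences["chr1"][12_345 : 12_345 + 101]
        m = map_wgs_read(read, index_100k, clip_len=76)
        assert m is not None and (m.chromosome, m.position, m.strand) == ("chr1", 12_345, "+")

    def test_two_copy_repeat_is_unmappable(self):
        seq = random_seq(5000, 33)
        dup = seq[1000:2000]
        genome = Genome({"chr1": seq[:3000] + dup + seq[3000:]})
        idx = build_index(genome)
        read = dup[200 : 200 + 101]
        assert map_wgs_read(read, idx, clip_len=76) is None

    def test_short_read_returns_none(self, index_100k):
        assert map_wgs_read("ACGT" * 10, index_100k, clip_len=76) is None

    def test_wgs_dedup_by_position(self):
        maps = [mk("chr1", 100), mk("chr1", 100), mk("chr1", 100, strand="-")]
        assert len(dedup_wgs_maps(maps)) == 2

    def test_less_than_one_map_per_pair(self, sim_bundle):
        """WGS averages < 1 countable map per read pair (uniqueness and
        duplicate losses leave at most one map from read 1)."""
        s = sim_bundle.wgs_stats
        assert 0 < s["maps_countable"] / s["pairs_in"] < 1


def test_kept_maps_fall_inside_true_fragments():
    """On error-free SMASH reads, ≥99% of countable maps lie within the
    originating fragment's interval (±3 bp junction slack)."""
    cfg = SimulationConfig(seed=9, genome=GenomeSpec(chromosomes=(("chr1", 500_000),)))
    cfg.smash.error_rate = 0.0
    cfg.smash.duplicate_rate = 0.0
    genome, _ = simulate_genome(cfg.genome, cfg.seed)
    idx = build_index(genome)
    weights = spike_cnvs(genome, [], "male")
    pairs, truth = simulate_smash_reads(genome, weights, cfg, 400)
    inside = total = 0
    by_mol = dict(tuple(truth.fragments.groupby("molecule")))
    for rid, r1, r2 in pairs:
        mol = int(rid[2:9])
        frs = by_mol[mol]
        for m in map_read_pair(r1, r2, idx, LKRule(20, 4)):
            total += 1
            ok = (
                (frs.chrom == m.chromosome)
                & (frs.start - 3 <= m.position)
                & (frs.start + frs.length + 3 >= m.position + m.length)
            ).any()
            inside += bool(ok)
    assert total > 1000
    assert inside / total >= 0.99
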