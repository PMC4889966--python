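"""Shared fixtures: small brute-forceable genomes and one medium
simulation bundle reused across test modules (built once per session)."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Set, Tuple

import numpy as np
import pytest

from smashcn.binning import BinScheme, bin_gc, count_maps, make_bins, mappability_mask
from smashcn.genome import Genome, revcomp
from smashcn.index import SuffixIndex, build_index
from smashcn.mapping import LKRule
from smashcn.pipeline import counts_to_track, map_smash_pairs, map_wgs_pairs
from smashcn.simulator import (
    GenomeSpec,
    SimulationConfig,
    simulate_genome,
    simulate_smash_reads,
    simulate_wgs_reads,
    spike_cnvs,
)


def random_seq(n: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return np.frombuffer(b"ACGT", dtype=np.uint8)[
        rng.integers(0, 4, size=n)
    ].tobytes().decode("ascii")


# ---------------------------------------------------------------- oracles


def brute_count(pattern: str, genome: Genome) -> int:
    """Occurrences of pattern in genome ⊕ reverse complement by scanning."""
    if not pattern or "N" in pattern:
        return 0
    total = 0
    for _, seq in genome.items():
        for text in (seq, revcomp(seq)):
            i = text.find(pattern)
            while i != -1:
                total += 1
                i = text.find(pattern, i + 1)
    return total


def brute_mams(read: str, genome: Genome, min_len: int) -> Set[Tuple[int, int]]:
    """All maximal substrings of the read with exactly one occurrence in
    genome ⊕ revcomp, by exhaustive enumeration; returns {(start, length)}."""
    out = set()
    q = len(read)
    for s in range(q):
        for l in range(min_len, q - s + 1):
            if brute_count(read[s : s + l], genome) != 1:
                continue
            if s > 0 and brute_count(read[s - 1 : s + l], genome) != 0:
                continue
            if s + l < q and brute_count(read[s : s + l + 1], genome) != 0:
                continue
            out.add((s, l))
    return out


# ---------------------------------------------------------------- fixtures


@pytest.fixture(scope="session")
def small_genome() -> Genome:
    """~7 kb two-chromosome genome with an N run — brute-forceable."""
    seq1 = random_seq(5000, 11)
    seq1 = seq1[:2000] + "N" * 30 + seq1[2030:]
    return Genome({"chr1": seq1, "chrX": random_seq(2000, 12)})


@pytest.fixture(scope="session")
def small_index(small_genome: Genome) -> SuffixIndex:
    return build_index(small_genome)


@pytest.fixture(scope="session")
def genome_100k() -> Genome:
    return Genome({"chr1": random_seq(80_000, 21), "chrX": random_seq(20_000, 22)})


@pytest.fixture(scope="session")
def index_100k(genome_100k: Genome) -> SuffixIndex:
    return build_index(genome_100k)


@dataclass
class SimBundle:
    """One CNV-bearing male genome with SMASH and WGS arms mapped and
    binned at >= 50 maps per bin."""

    config: SimulationConfig
    genome: Genome
    index: SuffixIndex
    weights: Dict[str, np.ndarray]
    cnvs: List[Tuple[str, int, int, int]]
    scheme: BinScheme
    smash_pairs: list
    smash_truth: object
    smash_maps: list
    smash_stats: dict
    wgs_maps: list
    wgs_stats: dict


CNVS_2MB = [
    ("chr1", 100_000, 220_000, 3),
    ("chr1", 400_000, 470_000, 1),
    ("chr1", 650_000, 700_000, 0),
    ("chr2", 150_000, 260_000, 4),
    ("chr2", 500_000, 560_000, 6),
]


@pytest.fixture(scope="session")
def sim_bundle() -> SimBundle:
    cfg = SimulationConfig(
        seed=42,
        genome=GenomeSpec(
            chromosomes=(("chr1", 900_000), ("chr2", 700_000), ("chrX", 400_000))
        ),
        cnvs=CNVS_2MB,
        sex="male",
    )
    genome, _ = simulate_genome(cfg.genome, cfg.seed)
    index = build_index(genome)
    weights = spike_cnvs(genome, cfg.cnvs, cfg.sex)
    scheme = make_bins(mappability_mask(genome, index, k=50), 400)
    bin_gc(genome, scheme)

    n_smash = 5500  # ~5 maps/pair -> ~27k maps -> ~65 maps/bin
    pairs, truth = simulate_smash_reads(genome, weights, cfg, n_smash)
    smash_maps, smash_stats = map_smash_pairs(pairs, index, LKRule(20, 4), 10_000)

    n_wgs = 30_000
    wpairs, _wtruth = simulate_wgs_reads(genome, weights, cfg, n_wgs)
    wgs_maps, wgs_stats = map_wgs_pairs(wpairs, index, clip_len=76)

    return SimBundle(
        config=cfg,
        genome=genome,
        index=index,
        weights=weights,
        cnvs=list(CNVS_2MB),
        scheme=scheme,
        smash_pairs=pairs,
        smash_truth=truth,
        smash_maps=smash_maps,
        smash_stats=smash_stats,
        wgs_maps=wgs_maps,
        wgs_stats=wgs_stats,
    )
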