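"""Synthetic genomes, CNV truth, and SMASH/WGS read simulation.

The simulator produces the statistical structure the pipeline assumes:

* genomes with smoothly drifting GC composition (so GC LOESS has a real
  covariate), optional exact duplications (to exercise mappability);
* integer copy-number ground truth via per-position sampling weights;
* SMASH molecules — chimeric concatenations of short fragments (truncated
  normal lengths, mean 45 bp) size-selected to 300–700 bp — read as
  2x101/2x125/2x150 pairs with substitution errors and PCR duplicates;
* WGS molecules — contiguous 300–700 bp inserts — read the same way;
* per-bin multiplicative GC bias and a shared systematic per-bin noise
  field (lognormal, common to all samples of a "batch") so reference
  normalization has something to cancel.

All randomness flows from explicit seeds; identical configuration and seed
give byte-identical FASTQ output.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .genome import Genome, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# --------------------------------------------------------------------- #
# configuration


@dataclass
class FragmentSpec:
    """Truncated-normal SMASH fragment length law (bp)."""

    mean: float = 45.0
    sd: float = 10.0
    min_len: int = 20
    max_len: int = 150


@dataclass
class SmashSpec:
    fragment: FragmentSpec = field(default_factory=FragmentSpec)
    chimera_min: int = 300
    chimera_max: int = 700
    read_len: int = 125
    error_rate: float = 0.001
    duplicate_rate: float = 0.05


@dataclass
class WgsSpec:
    insert_min: int = 300
    insert_max: int = 700
    read_len: int = 125
    clip_len: int = 76
    error_rate: float = 0.001
    duplicate_rate: float = 0.05


@dataclass
class GenomeSpec:
    """Chromosome layout: list of (name, length); sex classes inferred from
    names (chrX/chrY).  `gc_amplitude` scales the smooth GC drift around
    0.5; `duplications` plants exact copies (src_chrom, src_start, length,
    dst_chrom, dst_start) for mappability tests."""

    chromosomes: Sequence[Tuple[str, int]] = (("chr1", 1_000_000),)
    gc_amplitude: float = 0.08
    gc_block: int = 2000
    duplications: Sequence[Tuple[str, int, int, str, int]] = ()


@dataclass
class BiasSpec:
    gc_coeff: float = 0.5  # fragment acceptance ∝ 1 + gc_coeff*(gc-0.5)
    systematic_sd: float = 0.1  # lognormal sigma of the shared per-block field
    systematic_block: int = 10_000
    batch_seed: int = 77  # shared across samples of one batch


@dataclass
class SimulationConfig:
    seed: int = 1
    genome: GenomeSpec = field(default_factory=GenomeSpec)
    cnvs: Sequence[Tuple[str, int, int, int]] = ()  # chrom, start, end, copy number
    sex: str = "male"
    smash: SmashSpec = field(default_factory=SmashSpec)
    wgs: WgsSpec = field(default_factory=WgsSpec)
    bias: BiasSpec = field(default_factory=BiasSpec)


@dataclass
class TruthTable:
    """Ground truth emitted alongside reads.

    fragments: one row per true fragment (pair_id, molecule, frag_index,
    chrom, start, length, strand, chimera_offset).  pairs: one row per
    emitted read pair (pair_id, molecule, is_duplicate).
    """

    fragments: pd.DataFrame
    pairs: pd.DataFrame

    @property
    def n_distinct_molecules(self) -> int:
        return int(self.pairs["molecule"].nunique())

    def multiplicity(self) -> pd.Series:
        return self.pairs.groupby("molecule").size()


# --------------------------------------------------------------------- #
# genome + weights


def simulate_genome(spec: GenomeSpec, seed: int) -> Tuple[Genome, Dict[str, np.ndarray]]:
    """Generate a genome with smoothly drifting GC; returns the genome and
    the per-position GC probability field used to draw it."""
    rng = np.random.default_rng(seed)
    seqs: Dict[str, str] = {}
    gc_fields: Dict[str, np.ndarray] = {}
    for name, length in spec.chromosomes:
        if length <= 0:
            raise ValueError(f"invalid chromosome length {length} for {name}")
        nblocks = -(-length // spec.gc_block)
        # AR(1) walk gives slow drift; clipped to keep compositions sane
        steps = rng.normal(size=nblocks)
        walk = np.empty(nblocks)
        acc = 0.0
        for i in range(nblocks):
            acc = 0.95 * acc + 0.3118 * steps[i]  # stationary sd ~= 1
            walk[i] = acc
        gc_block_vals = np.clip(0.5 + spec.gc_amplitude * walk, 0.25, 0.75)
        gc = np.repeat(gc_block_vals, spec.gc_block)[:length]
        u = rng.random(length)
        is_gc = u < gc
        half = rng.random(length) < 0.5
        codes = np.where(is_gc, np.where(half, 1, 2), np.where(half, 0, 3))
        seqs[name] = _BASES[codes].tobytes().decode("ascii")
        gc_fields[name] = gc
    for src_c, src_s, length, dst_c, dst_s in spec.duplications:
        block = seqs[src_c][src_s : src_s + length]
        s = seqs[dst_c]
        seqs[dst_c] = s[:dst_s] + block + s[dst_s + length :]
    return Genome(seqs), gc_fields


def spike_cnvs(
    genome: Genome,
    cnv_spec: Sequence[Tuple[str, int, int, int]],
    sex: str = "male",
) -> Dict[str, np.ndarray]:
    """Per-position sampling weights proportional to integer copy number.

    Baseline: autosomes 2 copies; X and Y 1 copy for males, X 2 / Y 0 for
    females.  CNV intervals (half-open, non-overlapping) override the
    baseline with their integer copy number.
    """
    spans: Dict[str, List[Tuple[int, int]]] = {}
    for chrom, s, e, c in cnv_spec:
        if chrom not in genome.sequences:
            raise ValueError(f"CNV on unknown chromosome {chrom!r}")
        if not (0 <= s < e <= genome.length(chrom)):
            raise ValueError(f"CNV interval ({chrom}:{s}-{e}) outside chromosome")
        if c < 0 or int(c) != c:
            raise ValueError(f"copy number must be a non-negative integer, got {c}")
        for s2, e2 in spans.get(chrom, []):
            if max(s, s2) < min(e, e2):
                raise ValueError(f"overlapping CNV intervals on {chrom}")
        spans.setdefault(chrom, []).append((s, e))
    weights: Dict[str, np.ndarray] = {}
    for name in genome.names:
        cls = genome.sex_class[name]
        if cls == "autosome":
            base = 2.0
        elif cls == "X":
            base = 1.0 if sex == "male" else 2.0
        else:
            base = 1.0 if sex == "male" else 0.0
        w = np.full(genome.length(name), base, dtype=np.float32)
        weights[name] = w
    for chrom, s, e, c in cnv_spec:
        weights[chrom][s:e] = float(c)
    return weights


def systematic_field(genome: Genome, bias: BiasSpec) -> Dict[str, np.ndarray]:
    """Shared multiplicative per-block noise field (lognormal), generated
    from the batch seed so all samples of a batch see the same field."""
    rng = np.random.default_rng(bias.batch_seed)
    fields: Dict[str, np.ndarray] = {}
    for name in genome.names:
        L = genome.length(name)
        nblocks = -(-L // bias.systematic_block)
        block_vals = rng.lognormal(mean=0.0, sigma=bias.systematic_sd, size=nblocks)
        fields[name] = np.repeat(block_vals, bias.systematic_block)[:L].astype(np.float32)
    return fields


class _PositionSampler:
    """Samples genomic positions with probability proportional to a
    per-position weight array."""

    def __init__(self, genome: Genome, weights: Dict[str, np.ndarray]):
        self.names = list(genome.names)
        self.lengths = np.array([genome.length(n) for n in self.names], dtype=np.int64)
        self.offsets = np.concatenate([[0], np.cumsum(self.lengths)])
        w = np.concatenate([weights[n].astype(np.float64) for n in self.names])
        total = w.sum()
        if total <= 0:
            raise ValueError("all sampling weights are zero")
        self.cum = np.cumsum(w)
        self.total = total

    def sample(self, n: int, rng: np.random.Generator) -> Tuple[np.ndarray, np.ndarray]:
        u = rng.random(n) * self.total
        flat = np.searchsorted(self.cum, u, side="right")
        ci = np.searchsorted(self.offsets, flat, side="right") - 1
        return ci.astype(np.int64), flat - self.offsets[ci]


def _gc_cumsums(genome: Genome) -> Dict[str, np.ndarray]:
    out = {}
    for name, seq in genome.items():
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        isgc = ((arr == ord("G")) | (arr == ord("C"))).astype(np.int64)
        out[name] = np.concatenate([[0], np.cumsum(isgc)])
    return out


def _truncnorm_lengths(spec: FragmentSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    out = np.empty(n, dtype=np.int64)
    filled = 0
    while filled < n:
        draw = rng.normal(spec.mean, spec.sd, size=2 * (n - filled))
        ok = draw[(draw >= spec.min_len) & (draw <= spec.max_len)]
        take = min(ok.size, n - filled)
        out[filled : filled + take] = np.round(ok[:take]).astype(np.int64)
        filled += take
    return out


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    n = len(seq)
    k = rng.binomial(n, rate)
    if k == 0:
        return seq
    pos = rng.choice(n, size=k, replace=False)
    arr = bytearray(seq, "ascii")
    for p in pos:
        cur = arr[p]
        choices = [b for b in b"ACGT" if b != cur]
        arr[p] = choices[rng.integers(0, len(choices))]
    return arr.decode("ascii")


# --------------------------------------------------------------------- #
# read simulation


class _FragmentStream:
    """Draws accepted fragments in vectorized batches: position by copy
    weight x systematic field, length truncated-normal, random strand, GC
    acceptance 1 + beta*(gc - 0.5)."""

    def __init__(
        self,
        genome: Genome,
        weights: Dict[str, np.ndarray],
        frag: FragmentSpec,
        bias: BiasSpec,
        rng: np.random.Generator,
    ):
        eff = {}
        sysf = systematic_field(genome, bias)
        for name in genome.names:
            eff[name] = weights[name] * sysf[name]
        self.sampler = _PositionSampler(genome, eff)
        self.genome = genome
        self.frag = frag
        self.beta = bias.gc_coeff
        self.rng = rng
        self.gc_csum = _gc_cumsums(genome)
        self.chrom_len = {n: genome.length(n) for n in genome.names}
        self._buf: List[Tuple[str, int, int, str]] = []

    def _refill(self, n: int = 4096) -> None:
        rng = self.rng
        ci, pos = self.sampler.sample(n, rng)
        lens = _truncnorm_lengths(self.frag, n, rng)
        strands = rng.random(n) < 0.5
        accept_u = rng.random(n)
        amax = 1.0 + 0.5 * abs(self.beta)
        for c, p, l, st, au in zip(ci, pos, lens, strands, accept_u):
            name = self.sampler.names[c]
            if p + l > self.chrom_len[name]:
                continue
            cs = self.gc_csum[name]
            gc = (cs[p + l] - cs[p]) / l
            if au * amax > 1.0 + self.beta * (gc - 0.5):
                continue
            self._buf.append((name, int(p), int(l), "-" if st else "+"))

    def next(self) -> Tuple[str, int, int, str]:
        while not self._buf:
            self._refill()
        return self._buf.pop()


def simulate_smash_reads(
    genome: Genome,
    weights: Dict[str, np.ndarray],
    config: SimulationConfig,
    n_pairs: int,
) -> Tuple[List[Tuple[str, str, str]], TruthTable]:
    """Simulate SMASH read pairs.

    Returns (pairs, truth) where pairs is a list of (pair_id, read1, read2)
    and truth records every true fragment of every distinct molecule plus
    the molecule of every emitted pair (PCR duplicates re-read an existing
    molecule with independent sequencing errors).
    """
    spec = config.smash
    rng = np.random.default_rng(config.seed)
    stream = _FragmentStream(genome, weights, spec.fragment, config.bias, rng)
    molecules: List[Tuple[str, List[Tuple[str, int, int, str, int]]]] = []
    frag_rows = []
    pair_rows = []
    pairs_out: List[Tuple[str, str, str]] = []
    for pe in range(n_pairs):
        if molecules and rng.random() < spec.duplicate_rate:
            mol_idx = int(rng.integers(0, len(molecules)))
            is_dup = True
        else:
            mol_idx = len(molecules)
            is_dup = False
            chim, frags = _build_chimera(genome, stream, spec, rng)
            molecules.append((chim, frags))
            for fi, (chrom, p, l, st, off) in enumerate(frags):
                frag_rows.append((mol_idx, fi, chrom, p, l, st, off))
        chim, frags = molecules[mol_idx]
        pair_id = f"sm{mol_idx:07d}e{pe:07d}"
        r1 = _apply_errors(chim[: spec.read_len], spec.error_rate, rng)
        r2 = _apply_errors(revcomp(chim)[: spec.read_len], spec.error_rate, rng)
        pairs_out.append((pair_id, r1, r2))
        pair_rows.append((pair_id, mol_idx, is_dup))
    fragments = pd.DataFrame(
        frag_rows,
        columns=["molecule", "frag_index", "chrom", "start", "length", "strand", "chimera_offset"],
    )
    pairs = pd.DataFrame(pair_rows, columns=["pair_id", "molecule", "is_duplicate"])
    return pairs_out, TruthTable(fragments=fragments, pairs=pairs)


def _build_chimera(genome, stream, spec: SmashSpec, rng) -> Tuple[str, List]:
    while True:
        parts: List[str] = []
        frags: List[Tuple[str, int, int, str, int]] = []
        total = 0
        while total < spec.chimera_min:
            chrom, p, l, strand = stream.next()
            seq = genome.sequences[chrom][p : p + l]
            if strand == "-":
                seq = revcomp(seq)
            frags.append((chrom, p, l, strand, total))
            parts.append(seq)
            total += l
        if total <= spec.chimera_max:
            return "".join(parts), frags
        # overshot the size-selection window: discard and rebuild


def simulate_wgs_reads(
    genome: Genome,
    weights: Dict[str, np.ndarray],
    config: SimulationConfig,
    n_pairs: int,
) -> Tuple[List[Tuple[str, str, str]], TruthTable]:
    """Simulate conventional WGS read pairs: contiguous inserts of
    insert_min..insert_max bp sampled by copy weight, reads from the two
    insert ends, same error and duplicate model as the SMASH arm."""
    spec = config.wgs
    rng = np.random.default_rng(config.seed + 1)
    sysf = systematic_field(genome, config.bias)
    eff = {n: weights[n] * sysf[n] for n in genome.names}
    sampler = _PositionSampler(genome, eff)
    chrom_len = {n: genome.length(n) for n in genome.names}
    molecules: List[Tuple[str, str, int, int]] = []  # (insert_seq, chrom, start, ilen)
    frag_rows = []
    pair_rows = []
    pairs_out: List[Tuple[str, str, str]] = []
    for pe in range(n_pairs):
        if molecules and rng.random() < spec.duplicate_rate:
            mol_idx = int(rng.integers(0, len(molecules)))
            is_dup = True
        else:
            mol_idx = len(molecules)
            is_dup = False
            while True:
                ci, pos = sampler.sample(1, rng)
                name = sampler.names[int(ci[0])]
                p = int(pos[0])
                ilen = int(rng.integers(spec.insert_min, spec.insert_max + 1))
                if p + ilen <= chrom_len[name]:
                    break
            molecules.append((genome.sequences[name][p : p + ilen], name, p, ilen))
            frag_rows.append((mol_idx, 0, name, p, ilen, "+", 0))
        insert, name, p, ilen = molecules[mol_idx]
        pair_id = f"wg{mol_idx:07d}e{pe:07d}"
        r1 = _apply_errors(insert[: spec.read_len], spec.error_rate, rng)
        r2 = _apply_errors(revcomp(insert)[: spec.read_len], spec.error_rate, rng)
        pairs_out.append((pair_id, r1, r2))
        pair_rows.append((pair_id, mol_idx, is_dup))
    fragments = pd.DataFrame(
        frag_rows,
        columns=["molecule", "frag_index", "chrom", "start", "length", "strand", "chimera_offset"],
    )
    pairs = pd.DataFrame(pair_rows, columns=["pair_id", "molecule", "is_duplicate"])
    return pairs_out, TruthTable(fragments=fragments, pairs=pairs)


# --------------------------------------------------------------------- #
# FASTQ output


def write_fastq_pairs(
    pairs: Sequence[Tuple[str, str, str]], path1: str, path2: str
) -> None:
    """Write read pairs as standard 4-line FASTQ (gzip if *.gz); constant
    high base qualities, since the mapper is quality-blind."""
    op = gzip.open if str(path1).endswith(".gz") else open
    with op(path1, "wt") as f1:
        op2 = gzip.open if str(path2).endswith(".gz") else open
        with op2(path2, "wt") as f2:
            for rid, r1, r2 in pairs:
                f1.write(f"@{rid}/1\n{r1}\n+\n{'I' * len(r1)}\n")
                f2.write(f"@{rid}/2\n{r2}\n+\n{'I' * len(r2)}\n")
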