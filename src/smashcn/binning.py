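"""Equal-mappability bins and map counting.

Copy-number bins are chosen so every bin carries the same expected unique-map
content when the reference itself is sequenced exhaustively: bin boundaries
are placed so each bin contains the same number (±1) of positions whose
50-mer occurs exactly once in the genome plus its reverse complement.  Bins
never span chromosomes.  Per-bin GC fractions feed the LOESS correction and
a robust upward-outlier test masks "bad" bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genome import Genome
from .index import SuffixIndex
from .mapping import MapRecord


def mappability_mask(genome: Genome, index: SuffixIndex, k: int = 50) -> Dict[str, np.ndarray]:
    """Per-position 0/1 mask: 1 iff the k-mer starting there occurs exactly
    once in genome ⊕ reverse complement and contains no N.

    Positions within k-1 of a chromosome end are 0 (no full k-mer starts
    there).
    """
    masks: Dict[str, np.ndarray] = {}
    lcp = index.lcp
    lcp_next = np.append(lcp[1:], 0)
    for j in range(len(index.piece_start)):
        if index.piece_strand[j] != 1:
            continue
        chrom = index.names[index.piece_chrom[j]]
        start = int(index.piece_start[j])
        length = int(index.piece_len[j])
        mask = np.zeros(length, dtype=np.uint8)
        if length >= k:
            offs = np.arange(start, start + length - k + 1)
            r = index.isa[offs]
            unique = (lcp[r] < k) & (lcp_next[r] < k)
            # exclude windows containing N (or separators, impossible here)
            bases = index.bases[start : start + length]
            acgt = ((bases >= 1) & (bases <= 4)).astype(np.int64)
            csum = np.concatenate([[0], np.cumsum(acgt)])
            full = (csum[k:] - csum[:-k]) == k
            mask[: length - k + 1] = (unique & full).astype(np.uint8)
        masks[chrom] = mask
    return masks


@dataclass
class BinScheme:
    """Ordered half-open genomic intervals of equal expected unique-k-mer
    content, with per-bin GC fraction and a bad-bin mask."""

    table: pd.DataFrame  # columns: chrom, start, end, expected_count, gc, bad

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "expected_count"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"bin table missing columns {sorted(missing)}")
        if "gc" not in self.table.columns:
            self.table["gc"] = np.nan
        if "bad" not in self.table.columns:
            self.table["bad"] = False

    def __len__(self) -> int:
        return len(self.table)

    @property
    def chroms(self) -> List[str]:
        return list(dict.fromkeys(self.table["chrom"]))

    def good(self) -> np.ndarray:
        return ~self.table["bad"].to_numpy()

    def autosome_bins(self, genome: Genome) -> np.ndarray:
        sex = self.table["chrom"].map(genome.sex_class)
        return (sex == "autosome").to_numpy()

    def save(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def load(cls, path: str) -> "BinScheme":
        return cls(pd.read_csv(path, sep="\t"))


def make_bins(masks: Dict[str, np.ndarray], n_bins: int) -> BinScheme:
    """Build n_bins equal-content bins from a per-position mappability mask.

    Every bin holds floor(T/n) or ceil(T/n) mappable positions, where T is
    the genome-wide mappable total; bins tile each chromosome completely and
    never cross chromosome boundaries.  Bin count per chromosome is chosen
    so the ±1 guarantee holds globally; boundaries are placed after the
    appropriate cumulative quantile of mappable positions.
    """
    totals = {c: int(m.sum()) for c, m in masks.items()}
    T = sum(totals.values())
    if T < n_bins:
        raise ValueError(f"n_bins={n_bins} exceeds total mappable positions {T}")
    q, r = divmod(T, n_bins)  # r bins get q+1
    n_c = _allocate_bins(totals, n_bins, q)
    rows = []
    for chrom, mask in masks.items():
        nc = n_c[chrom]
        tc = totals[chrom]
        if nc == 0:
            # chromosome with no bin of its own: fold into a single
            # zero-content bin (possible only when tc == 0 and q > 0)
            rows.append((chrom, 0, len(mask), 0))
            continue
        if nc * q <= tc <= nc * (q + 1):
            # global ±1 achievable: rc bins of q+1, rest q, heavy first
            rc = tc - nc * q
            counts = [q + 1] * rc + [q] * (nc - rc)
        else:
            # chromosome boundaries make the global quotient infeasible;
            # fall back to the per-chromosome ±1 split at the same density
            qc, rc = divmod(tc, nc)
            counts = [qc + 1] * rc + [qc] * (nc - rc)
        pos = np.flatnonzero(mask)
        cuts = np.cumsum(counts)[:-1]
        starts = [0]
        for cut in cuts:
            starts.append(int(pos[cut]))  # bin starts at its first mappable position
        ends = starts[1:] + [len(mask)]
        for s, e, cnt in zip(starts, ends, counts):
            rows.append((chrom, s, e, cnt))
    table = pd.DataFrame(rows, columns=["chrom", "start", "end", "expected_count"])
    return BinScheme(table)


def _allocate_bins(totals: Dict[str, int], n_bins: int, q: int) -> Dict[str, int]:
    """Per-chromosome bin counts summing to n_bins.

    Prefers counts compatible with the global quotient (n_c*q <= T_c <=
    n_c*(q+1), making every bin floor or ceil of T/n genome-wide); when
    chromosome boundaries make that infeasible, falls back to proportional
    largest-remainder allocation, and make_bins applies the ±1 split per
    chromosome instead.
    """
    chroms = list(totals)
    T = sum(totals.values())
    if q > 0:
        n_c = {c: -(-totals[c] // (q + 1)) for c in chroms}  # ceil division
        deficit = n_bins - sum(n_c.values())
        if deficit >= 0:
            for c in sorted(chroms, key=lambda c: -totals[c]):
                if deficit == 0:
                    break
                room = max(0, totals[c] // q - n_c[c])
                take = min(room, deficit)
                n_c[c] += take
                deficit -= take
            if deficit == 0:
                return n_c
    # proportional fallback (largest remainder), at least one bin per
    # chromosome with mappable content
    exact = {c: totals[c] * n_bins / T for c in chroms}
    n_c = {c: max(1, int(exact[c])) if totals[c] > 0 else 0 for c in chroms}
    n_c = {c: min(n_c[c], totals[c]) for c in chroms}
    rem = n_bins - sum(n_c.values())
    if rem < 0:
        raise ValueError("cannot allocate bins (too many chromosomes for n_bins)")
    order = sorted(chroms, key=lambda c: -(exact[c] - int(exact[c])))
    i = 0
    while rem > 0:
        c = order[i % len(order)]
        if n_c[c] < totals[c]:
            n_c[c] += 1
            rem -= 1
        i += 1
        if i > 10 * len(order) * (rem + 1):
            raise ValueError("bin allocation infeasible for this mask; reduce n_bins")
    return n_c


def bin_gc(genome: Genome, scheme: BinScheme) -> np.ndarray:
    """Per-bin GC fraction (G+C)/(A+C+G+T) over reference bases; all-N bins
    get NaN and are flagged bad."""
    gcs = np.empty(len(scheme))
    bad = scheme.table["bad"].to_numpy().copy()
    for i, row in enumerate(scheme.table.itertuples(index=False)):
        seq = genome.sequences[row.chrom][row.start : row.end]
        at = seq.count("A") + seq.count("T")
        gc = seq.count("G") + seq.count("C")
        if at + gc == 0:
            gcs[i] = np.nan
            bad[i] = True
        else:
            gcs[i] = gc / (at + gc)
    scheme.table["gc"] = gcs
    scheme.table["bad"] = bad
    return gcs


@dataclass
class BinCounts:
    """Per-bin countable-map counts for one sample."""

    counts: np.ndarray
    sample: str = ""
    dropped: int = 0  # maps on chromosomes absent from the scheme

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def count_maps(maps: Sequence[MapRecord], scheme: BinScheme, sample: str = "") -> BinCounts:
    """Assign each map's anchor (leftmost reference base) to its bin."""
    starts: Dict[str, np.ndarray] = {}
    offsets: Dict[str, np.ndarray] = {}
    for chrom in scheme.chroms:
        sub = scheme.table[scheme.table["chrom"] == chrom]
        starts[chrom] = sub["start"].to_numpy()
        offsets[chrom] = sub.index.to_numpy()
    counts = np.zeros(len(scheme), dtype=np.int64)
    dropped = 0
    for m in maps:
        if m.chromosome not in starts:
            dropped += 1
            continue
        s = starts[m.chromosome]
        j = int(np.searchsorted(s, m.position, side="right") - 1)
        counts[offsets[m.chromosome][j]] += 1
    return BinCounts(counts=counts, sample=sample, dropped=dropped)


def mask_bad_bins(
    count_list: Sequence[BinCounts],
    scheme: BinScheme,
    genome: Genome,
    p: float = 0.05,
) -> BinScheme:
    """Mask bins whose summed normalized count deviates UPWARD from the
    chromosome median by more than a MAD-based, Bonferroni-corrected limit.

    Each sample's counts are mean-normalized (autosome mean 1, +1
    pseudocount) before bin-wise summation; a bin is bad when
    (value - chrom median) / (1.4826 * MAD) exceeds the upper-tail normal
    quantile at p / n_bins.  Downward deviations are never masked.
    """
    if not count_list:
        raise ValueError("need at least one sample")
    auto = scheme.autosome_bins(genome)
    total = np.zeros(len(scheme))
    for bc in count_list:
        v = bc.counts.astype(float) + 1.0
        m = v[auto].mean()
        total += v / m
    z = sps.norm.ppf(1 - p / len(scheme))
    bad = scheme.table["bad"].to_numpy().copy()
    chrom_arr = scheme.table["chrom"].to_numpy()
    for chrom in scheme.chroms:
        sel = chrom_arr == chrom
        vals = total[sel]
        med = np.median(vals)
        mad = np.median(np.abs(vals - med))
        if mad == 0:
            raise ValueError(
                f"MAD of summed counts is zero on {chrom}; increase count depth"
            )
        dev = (vals - med) / (1.4826 * mad)
        bad[sel] |= dev > z
    out = BinScheme(scheme.table.copy())
    out.table["bad"] = bad
    return out


def true_bin_copy_number(
    scheme: BinScheme,
    genome: Genome,
    cnv_spec: Sequence[Tuple[str, int, int, int]],
    sex: str = "male",
) -> np.ndarray:
    """Length-weighted true copy number of each bin given a CNV spec
    (chrom, start, end, integer copy number) on a baseline diploid genome
    (X and Y at 1 copy for males)."""
    base = {}
    for name in genome.names:
        cls = genome.sex_class[name]
        if cls == "autosome":
            base[name] = 2.0
        elif cls == "X":
            base[name] = 1.0 if sex == "male" else 2.0
        else:
            base[name] = 1.0 if sex == "male" else 0.0
    cn = np.empty(len(scheme))
    for i, row in enumerate(scheme.table.itertuples(index=False)):
        value = base[row.chrom]
        width = row.end - row.start
        acc = value * width
        for chrom, s, e, c in cnv_spec:
            if chrom != row.chrom:
                continue
            ov = min(e, row.end) - max(s, row.start)
            if ov > 0:
                acc += (c - value) * ov
        cn[i] = acc / width
    return cn
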