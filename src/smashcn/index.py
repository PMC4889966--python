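"""Suffix-array index over a genome plus its reverse complement.

The index concatenates every chromosome and every reverse-complemented
chromosome into one text, separated by per-boundary sentinel symbols, and
holds the suffix array, its inverse and the LCP table over that text.  It
answers two questions used throughout the pipeline:

* how many times does a pattern occur in the genome and its reverse
  complement (:meth:`SuffixIndex.occurrence_count`), and
* what are the maximal almost-unique matches (MAMs) of a read — maximal
  substrings of the read occurring exactly once in the indexed text
  (:meth:`SuffixIndex.find_mams`).

Placing both strands in a single text means a read is queried once, in its
given orientation, and minus-strand matches surface through the
reverse-complement half of the text.

Encoding: A,C,G,T map to codes 1..4; every N and every separator receives
its own unique code >= 5.  A query N is encoded as 0, which occurs nowhere
in the text, so N never participates in a match on either side.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
from numba import njit

from .genome import Genome, revcomp

INDEX_FORMAT_VERSION = 1

_BASE_CODE = {"A": 1, "C": 2, "G": 3, "T": 4}

# byte-class array values (parallel `bases` array, used for N-window tests)
BASE_N = 0
BASE_SEP = 5


@dataclass(frozen=True)
class MAMatch:
    """One maximal almost-unique match of a read against the index."""

    query_start: int
    length: int
    chromosome: str
    position: int  # 0-based leftmost matched reference base
    strand: str  # '+' or '-'


def _suffix_array_doubling(codes: np.ndarray) -> np.ndarray:
    """Suffix array by prefix doubling (numpy lexsort); O(n log^2 n)."""
    n = codes.size
    rank = np.unique(codes, return_inverse=True)[1].astype(np.int64)
    k = 1
    order = np.argsort(rank, kind="stable")
    while True:
        key2 = np.full(n, -1, dtype=np.int64)
        key2[: n - k] = rank[k:]
        order = np.lexsort((key2, rank))
        r1 = rank[order]
        r2 = key2[order]
        changed = np.empty(n, dtype=np.int64)
        changed[0] = 0
        changed[1:] = (r1[1:] != r1[:-1]) | (r2[1:] != r2[:-1])
        new_rank = np.cumsum(changed)
        rank = np.empty(n, dtype=np.int64)
        rank[order] = new_rank
        if new_rank[-1] == n - 1 or k >= n:
            break
        k *= 2
    return order.astype(np.int32)


@njit(cache=True)
def _kasai_lcp(codes, sa, isa):  # pragma: no cover - numba
    n = sa.size
    lcp = np.zeros(n, dtype=np.int32)
    h = 0
    for i in range(n):
        r = isa[i]
        if r > 0:
            j = sa[r - 1]
            while i + h < n and j + h < n and codes[i + h] == codes[j + h]:
                h += 1
            lcp[r] = h
            if h > 0:
                h -= 1
        else:
            h = 0
    return lcp


@njit(cache=True)
def _narrow(codes, sa, lo, hi, d, c):  # pragma: no cover - numba
    """Restrict SA interval [lo,hi) (suffixes sharing a d-prefix) to those
    whose d-th character equals c; returns the new (lo, hi)."""
    n = codes.size
    # lower bound: first m with char >= c
    a, b = lo, hi
    while a < b:
        m = (a + b) // 2
        p = sa[m] + d
        ch = codes[p] if p < n else -1
        if ch < c:
            a = m + 1
        else:
            b = m
    new_lo = a
    # upper bound: first m with char > c
    a, b = new_lo, hi
    while a < b:
        m = (a + b) // 2
        p = sa[m] + d
        ch = codes[p] if p < n else -1
        if ch <= c:
            a = m + 1
        else:
            b = m
    return new_lo, a


@njit(cache=True)
def _pattern_interval(codes, sa, pat):  # pragma: no cover - numba
    """SA interval of the full pattern; (lo, hi, matched_len)."""
    lo, hi = 0, sa.size
    for d in range(pat.size):
        lo, hi = _narrow(codes, sa, lo, hi, d, pat[d])
        if lo >= hi:
            return lo, hi, d
    return lo, hi, pat.size


@njit(cache=True)
def _matching_stats(codes, sa, query):  # pragma: no cover - numba
    """Per-position longest-match lengths, counts and one match offset.

    For each query position i: the length l of the longest substring
    query[i:i+l] occurring in the text, the number of its occurrences, and
    the text offset of its first (SA-ordered) occurrence.
    """
    q = query.size
    lens = np.zeros(q, dtype=np.int64)
    cnts = np.zeros(q, dtype=np.int64)
    offs = np.full(q, -1, dtype=np.int64)
    for i in range(q):
        lo, hi = 0, sa.size
        d = 0
        while i + d < q:
            nlo, nhi = _narrow(codes, sa, lo, hi, d, query[i + d])
            if nlo >= nhi:
                break
            lo, hi = nlo, nhi
            d += 1
        lens[i] = d
        if d > 0:
            cnts[i] = hi - lo
            offs[i] = sa[lo]
    return lens, cnts, offs


def encode_query(seq: str) -> np.ndarray:
    """Encode a read: ACGT -> 1..4, anything else -> 0 (matches nothing)."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.zeros(arr.size, dtype=np.int32)
    out[arr == ord("A")] = 1
    out[arr == ord("C")] = 2
    out[arr == ord("G")] = 3
    out[arr == ord("T")] = 4
    return out


class SuffixIndex:
    """Suffix array + inverse + LCP over genome ⊕ reverse complement.

    Attributes
    ----------
    codes : int32 array
        Encoded text (see module docstring).
    bases : uint8 array
        Parallel byte classes: 1..4 = ACGT, 0 = N, 5 = separator.
    sa, isa, lcp : int32 arrays
        Suffix array, inverse suffix array, and LCP table where ``lcp[i]``
        is the longest common prefix of the suffixes at ``sa[i-1]`` and
        ``sa[i]`` (``lcp[0] == 0``).
    """

    def __init__(self, genome: Genome):
        self.genome = genome
        self._build_text(genome)
        self.sa = _suffix_array_doubling(self.codes)
        self.isa = np.empty_like(self.sa)
        self.isa[self.sa] = np.arange(self.sa.size, dtype=np.int32)
        self.lcp = _kasai_lcp(self.codes, self.sa.astype(np.int64), self.isa.astype(np.int64))

    def _build_text(self, genome: Genome) -> None:
        names = list(genome.names)
        pieces: List[Tuple[str, str, str]] = []  # (chrom, strand, seq)
        for n in names:
            pieces.append((n, "+", genome.sequences[n]))
        for n in names:
            pieces.append((n, "-", revcomp(genome.sequences[n])))
        total = sum(len(s) for _, _, s in pieces) + len(pieces)
        codes = np.empty(total, dtype=np.int32)
        bases = np.empty(total, dtype=np.uint8)
        piece_start = np.empty(len(pieces), dtype=np.int64)
        piece_len = np.empty(len(pieces), dtype=np.int64)
        pos = 0
        next_special = 5  # unique codes for every N and separator
        for j, (name, strand, seq) in enumerate(pieces):
            piece_start[j] = pos
            piece_len[j] = len(seq)
            arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
            enc = np.zeros(arr.size, dtype=np.int32)
            for base, code in _BASE_CODE.items():
                enc[arr == ord(base)] = code
            n_mask = enc == 0  # N positions
            n_count = int(n_mask.sum())
            if n_count:
                enc[n_mask] = np.arange(next_special, next_special + n_count, dtype=np.int32)
                next_special += n_count
            codes[pos : pos + arr.size] = enc
            b = enc.astype(np.uint8)
            b[enc > 4] = BASE_N
            bases[pos : pos + arr.size] = b
            pos += arr.size
            codes[pos] = next_special
            next_special += 1
            bases[pos] = BASE_SEP
            pos += 1
        self.codes = codes
        self.bases = bases
        self.piece_start = piece_start
        self.piece_len = piece_len
        self.piece_chrom = np.array(
            [names.index(n) for n, _, _ in pieces], dtype=np.int32
        )
        self.piece_strand = np.array(
            [1 if s == "+" else -1 for _, s, _ in pieces], dtype=np.int8
        )
        self.names = names

    # ------------------------------------------------------------------ #

    def locate(self, text_offset: int, length: int) -> Tuple[str, int, str]:
        """Map a text offset + match length to (chromosome, position, strand).

        Positions are 0-based leftmost reference base of the match; for
        minus-strand matches the offset within the reverse-complement piece
        is mirrored back into forward-genome coordinates.
        """
        j = int(np.searchsorted(self.piece_start, text_offset, side="right") - 1)
        within = text_offset - int(self.piece_start[j])
        if within + length > self.piece_len[j]:
            raise ValueError("match crosses a separator (corrupt index?)")
        chrom = self.names[self.piece_chrom[j]]
        if self.piece_strand[j] == 1:
            return chrom, int(within), "+"
        return chrom, int(self.piece_len[j] - within - length), "-"

    def occurrence_count(self, pattern: str) -> int:
        """Exact occurrence count of the pattern in genome ⊕ revcomp text."""
        if not pattern:
            raise ValueError("empty pattern")
        pat = encode_query(pattern)
        if (pat == 0).any():
            return 0
        lo, hi, matched = _pattern_interval(self.codes, self.sa, pat)
        return int(hi - lo) if matched == pat.size else 0

    def _occ_count_codes(self, pat: np.ndarray) -> int:
        if (pat == 0).any():
            return 0
        lo, hi, matched = _pattern_interval(self.codes, self.sa, pat)
        return int(hi - lo) if matched == pat.size else 0

    def matching_statistics(
        self, query_codes: np.ndarray
    ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        return _matching_stats(self.codes, self.sa, query_codes)

    def find_mams(self, read: str, min_len: int) -> List[MAMatch]:
        """All maximal substrings of the read occurring exactly once in the
        indexed text (genome plus reverse complement), length >= min_len.

        A substring qualifies when its occurrence count is 1 and any
        single-base extension within the read has count 0 (extensions
        leaving the read are vacuously maximal).  Output is sorted by
        query_start.
        """
        q = encode_query(read)
        if q.size < min_len:
            return []
        lens, cnts, offs = _matching_stats(self.codes, self.sa, q)
        out: List[MAMatch] = []
        for i in range(q.size):
            li = int(lens[i])
            if li < min_len or cnts[i] != 1:
                continue
            # left-maximality: the match starting one base earlier must not
            # cover this one (otherwise the extended substring also occurs)
            if i > 0 and lens[i - 1] > li:
                continue
            chrom, pos, strand = self.locate(int(offs[i]), li)
            out.append(MAMatch(i, li, chrom, pos, strand))
        return out

    # ------------------------------------------------------------------ #

    def save(self, path: str) -> None:
        """Serialize to a versioned .npz archive."""
        np.savez_compressed(
            path,
            version=np.int64(INDEX_FORMAT_VERSION),
            codes=self.codes,
            bases=self.bases,
            sa=self.sa,
            isa=self.isa,
            lcp=self.lcp,
            piece_start=self.piece_start,
            piece_len=self.piece_len,
            piece_chrom=self.piece_chrom,
            piece_strand=self.piece_strand,
            names=np.array(self.names, dtype=object),
            sex_class=np.array(
                [self.genome.sex_class[n] for n in self.names], dtype=object
            ),
            seqs=np.array([self.genome.sequences[n] for n in self.names], dtype=object),
        )

    @classmethod
    def load(cls, path: str) -> "SuffixIndex":
        with np.load(path, allow_pickle=True) as z:
            version = int(z["version"])
            if version != INDEX_FORMAT_VERSION:
                raise ValueError(f"unsupported index format version {version}")
            obj = cls.__new__(cls)
            names = [str(n) for n in z["names"]]
            seqs = [str(s) for s in z["seqs"]]
            sex = [str(s) for s in z["sex_class"]]
            obj.genome = Genome(dict(zip(names, seqs)), dict(zip(names, sex)))
            obj.names = names
            for key in (
                "codes",
                "bases",
                "sa",
                "isa",
                "lcp",
                "piece_start",
                "piece_len",
                "piece_chrom",
                "piece_strand",
            ):
                setattr(obj, key, z[key])
        return obj


def build_index(genome: Genome) -> SuffixIndex:
    """Build the suffix-array index over a genome and its reverse complement."""
    return SuffixIndex(genome)
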