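"""From per-read MAMs to countable maps.

A raw MAM can be an artifact of chimerism: the junction of two ligated
fragments can, by chance, form a string that is unique in the genome.  The
L:K rule guards against this by demanding that a MAM of length M remain
unique after K bases are trimmed from an end.  A 10-kb proximity filter then
collapses same-locus maps within a read pair (indel/SNP splits and
insert-end double reads), and PCR duplicates are removed using the multi-map
signature of the pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .index import MAMatch, SuffixIndex, encode_query


@dataclass(frozen=True)
class LKRule:
    """Map-acceptance rule: keep a MAM of length M iff M >= L and the
    length-(M-K) trims are still unique.

    mode 'both' requires both the left-trimmed and right-trimmed substrings
    to map uniquely; 'either' accepts if at least one does.
    """

    L: int = 20
    K: int = 4
    mode: str = "both"

    def __post_init__(self) -> None:
        if not (self.L > self.K >= 0):
            raise ValueError(f"require L > K >= 0, got {self.L}:{self.K}")
        if self.mode not in ("both", "either"):
            raise ValueError(f"unknown lk mode {self.mode!r}")


@dataclass(frozen=True)
class MapRecord:
    """One countable fragment map anchored at its leftmost reference base."""

    chromosome: str
    position: int
    strand: str
    length: int
    read_pair_id: str = ""
    query_start: int = 0
    mate: int = 1  # 1 or 2


PairSignature = Tuple[Tuple[str, int, str, int], ...]


def pair_signature(maps: Sequence[MapRecord]) -> PairSignature:
    """Canonical signature of a read pair: sorted (chrom, pos, strand, len)."""
    return tuple(sorted((m.chromosome, m.position, m.strand, m.length) for m in maps))


def lk_filter(
    mams: Sequence[MAMatch],
    rule: LKRule,
    index: SuffixIndex,
    read: str,
    read_pair_id: str = "",
    mate: int = 1,
) -> List[MapRecord]:
    """Apply the L:K rule to the MAMs of one read.

    The trims are taken from the read sequence itself: for a MAM covering
    read[s:s+M], the left trim is read[s+K:s+M] and the right trim
    read[s:s+M-K]; each must occur exactly once in the index.
    """
    out: List[MapRecord] = []
    q = encode_query(read)
    for m in mams:
        if m.length < rule.L:
            continue
        if rule.K > 0:
            s, e = m.query_start, m.query_start + m.length
            left_ok = index._occ_count_codes(q[s + rule.K : e]) == 1
            right_ok = index._occ_count_codes(q[s : e - rule.K]) == 1
            ok = (left_ok and right_ok) if rule.mode == "both" else (left_ok or right_ok)
            if not ok:
                continue
        out.append(
            MapRecord(
                chromosome=m.chromosome,
                position=m.position,
                strand=m.strand,
                length=m.length,
                read_pair_id=read_pair_id,
                query_start=m.query_start,
                mate=mate,
            )
        )
    return out


def proximity_filter(maps: Sequence[MapRecord], min_separation: int = 10000) -> List[MapRecord]:
    """Collapse same-chromosome maps of one read pair lying within
    min_separation of each other to a single representative.

    Maps are clustered transitively by anchor distance; the longest map of
    each cluster is kept (ties broken by leftmost position).  The result has
    no same-chromosome pair closer than min_separation.
    """
    by_chrom: Dict[str, List[MapRecord]] = {}
    for m in maps:
        by_chrom.setdefault(m.chromosome, []).append(m)
    kept: List[MapRecord] = []
    for chrom_maps in by_chrom.values():
        chrom_maps.sort(key=lambda m: m.position)
        cluster: List[MapRecord] = []
        for m in chrom_maps:
            if cluster and m.position - cluster[-1].position < min_separation:
                cluster.append(m)
            else:
                if cluster:
                    kept.append(_cluster_representative(cluster))
                cluster = [m]
        if cluster:
            kept.append(_cluster_representative(cluster))
    kept.sort(key=lambda m: (m.chromosome, m.position))
    return kept


def _cluster_representative(cluster: List[MapRecord]) -> MapRecord:
    return max(cluster, key=lambda m: (m.length, -m.position))


def dedup_pairs(
    pairs: Iterable[Tuple[str, List[MapRecord]]]
) -> List[Tuple[str, List[MapRecord]]]:
    """Retain one read pair per distinct map signature.

    Pairs with no countable maps are dropped.  The first pair carrying a
    given signature (input order) is the one retained, so the operation is
    idempotent.
    """
    seen: set = set()
    out: List[Tuple[str, List[MapRecord]]] = []
    for rid, maps in pairs:
        if not maps:
            continue
        sig = pair_signature(maps)
        if sig in seen:
            continue
        seen.add(sig)
        out.append((rid, maps))
    return out


def map_wgs_read(
    read: str,
    index: SuffixIndex,
    clip_len: int = 76,
    read_pair_id: str = "",
) -> Optional[MapRecord]:
    """Map a WGS read by exact-unique matching of its first clip_len bases.

    Returns a MapRecord when the clipped read occurs exactly once in the
    genome plus reverse complement, else None.  Mirrors single-end unique
    mapping of read 1 clipped to 76 bp.
    """
    if len(read) < clip_len:
        return None
    clipped = read[:clip_len]
    q = encode_query(clipped)
    if index._occ_count_codes(q) != 1:
        return None
    from .index import _pattern_interval  # local import to reuse numba kernel

    lo, hi, matched = _pattern_interval(index.codes, index.sa, q)
    chrom, pos, strand = index.locate(int(index.sa[lo]), clip_len)
    return MapRecord(
        chromosome=chrom,
        position=pos,
        strand=strand,
        length=clip_len,
        read_pair_id=read_pair_id,
    )


def dedup_wgs_maps(maps: Sequence[MapRecord]) -> List[MapRecord]:
    """WGS duplicate removal: one map per (chromosome, position, strand)."""
    seen: set = set()
    out: List[MapRecord] = []
    for m in maps:
        key = (m.chromosome, m.position, m.strand)
        if key in seen:
            continue
        seen.add(key)
        out.append(m)
    return out


def map_read_pair(
    read1: str,
    read2: str,
    index: SuffixIndex,
    rule: LKRule = LKRule(),
    min_separation: int = 10000,
    min_len: Optional[int] = None,
    read_pair_id: str = "",
) -> List[MapRecord]:
    """Full SMASH treatment of one read pair: MAMs on both mates, L:K
    filter, then the cross-mate proximity filter."""
    min_len = rule.L if min_len is None else min_len
    maps: List[MapRecord] = []
    for mate, read in ((1, read1), (2, read2)):
        mams = index.find_mams(read, min_len=min_len)
        maps.extend(lk_filter(mams, rule, index, read, read_pair_id=read_pair_id, mate=mate))
    return proximity_filter(maps, min_separation=min_separation)
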