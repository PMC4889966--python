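"""Pipeline driver: index → map → bin → count → normalize → segment → QC.

The defaults are the operating point of the method: 20:4 map rule, 10-kb
proximity separation, GC LOESS span 0.3, CBS with alpha 0.02 and minimum
segment length 3 bins.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import io as sio
from .binning import BinCounts, BinScheme, bin_gc, count_maps, make_bins, mappability_mask
from .genome import Genome, read_fasta
from .index import SuffixIndex, build_index
from .mapping import LKRule, MapRecord, dedup_pairs, dedup_wgs_maps, map_read_pair, map_wgs_read
from .normalization import RatioTrack, gc_correct, normalize_mean, reference_normalize, subsample_counts
from .qc_stats import qc_summary
from .segmentation import cbs_segment, quantal_fit

log = logging.getLogger("smashcn")


@dataclass
class PipelineConfig:
    fasta: str = ""
    fastq1: str = ""
    fastq2: str = ""
    reference_counts: Optional[str] = None
    out_dir: str = "smashcn_out"
    mode: str = "smash"  # or 'wgs'
    L: int = 20
    K: int = 4
    lk_mode: str = "both"
    min_separation: int = 10000
    wgs_clip_len: int = 76
    n_bins: int = 1000
    kmer: int = 50
    loess_span: float = 0.3
    cbs_alpha: float = 0.02
    cbs_min_seg: int = 3
    cbs_permutations: int = 10000
    quantal_s_bounds: Tuple[float, float] = (1.0, 4.0)
    quantal_o_bounds: Tuple[float, float] = (-0.4, 0.4)
    match_reference_depth: bool = False
    seed: int = 0
    sample: str = "sample"

    def validate(self) -> None:
        if not (self.L > self.K >= 0):
            raise ValueError("require L > K >= 0")
        if self.n_bins < 1:
            raise ValueError("n_bins must be positive")
        if self.mode not in ("smash", "wgs"):
            raise ValueError(f"unknown mode {self.mode!r}")


def map_smash_pairs(
    pairs,
    index: SuffixIndex,
    rule: LKRule = LKRule(),
    min_separation: int = 10000,
) -> Tuple[List[MapRecord], Dict[str, int]]:
    """Map, L:K-filter, proximity-filter and deduplicate SMASH read pairs.

    Returns the flat list of countable maps of retained (non-duplicate)
    pairs plus stage counters.
    """
    per_pair = []
    n_pairs = 0
    n_maps_prededup = 0
    for rid, r1, r2 in pairs:
        n_pairs += 1
        maps = map_read_pair(r1, r2, index, rule, min_separation, read_pair_id=rid)
        n_maps_prededup += len(maps)
        per_pair.append((rid, maps))
    retained = dedup_pairs(per_pair)
    flat = [m for _, maps in retained for m in maps]
    stats = {
        "pairs_in": n_pairs,
        "pairs_retained": len(retained),
        "maps_before_dedup": n_maps_prededup,
        "maps_countable": len(flat),
    }
    return flat, stats


def map_wgs_pairs(
    pairs,
    index: SuffixIndex,
    clip_len: int = 76,
) -> Tuple[List[MapRecord], Dict[str, int]]:
    """WGS arm: read 1 clipped, exact-unique mapped, position-deduplicated."""
    raw: List[MapRecord] = []
    n_pairs = 0
    for rid, r1, _r2 in pairs:
        n_pairs += 1
        m = map_wgs_read(r1, index, clip_len=clip_len, read_pair_id=rid)
        if m is not None:
            raw.append(m)
    maps = dedup_wgs_maps(raw)
    stats = {
        "pairs_in": n_pairs,
        "maps_before_dedup": len(raw),
        "maps_countable": len(maps),
    }
    return maps, stats


def counts_to_track(
    counts: BinCounts,
    scheme: BinScheme,
    genome: Genome,
    loess_span: float = 0.3,
    reference: Optional[BinCounts] = None,
    match_reference_depth: bool = False,
    seed: int = 0,
) -> RatioTrack:
    """Counts → mean-normalized → GC-corrected (→ reference-normalized)."""
    track = normalize_mean(counts, scheme, genome)
    track = gc_correct(track, scheme, genome, span=loess_span)
    if reference is not None:
        if match_reference_depth:
            reference = subsample_counts(reference, counts.total, seed=seed)
        ref_track = normalize_mean(reference, scheme, genome)
        ref_track = gc_correct(ref_track, scheme, genome, span=loess_span)
        track = reference_normalize(track, ref_track, scheme, genome)
    return track


def run_pipeline(config: PipelineConfig) -> Dict[str, object]:
    """Execute the full pipeline from files; writes every intermediate
    artifact into config.out_dir and returns the in-memory results."""
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    t_start = time.time()

    genome = read_fasta(config.fasta)
    log.info("genome: %d chromosomes, %d bp", len(genome.names), genome.total_length)
    index = build_index(genome)
    log.info("index built in %.1fs", time.time() - t_start)

    masks = mappability_mask(genome, index, k=config.kmer)
    scheme = make_bins(masks, config.n_bins)
    bin_gc(genome, scheme)
    scheme.save(os.path.join(config.out_dir, "bins.bed"))

    pairs = sio.read_fastq_pairs(config.fastq1, config.fastq2)
    t0 = time.time()
    if config.mode == "smash":
        rule = LKRule(config.L, config.K, config.lk_mode)
        maps, stats = map_smash_pairs(pairs, index, rule, config.min_separation)
    else:
        maps, stats = map_wgs_pairs(pairs, index, clip_len=config.wgs_clip_len)
    log.info("mapping: %s in %.1fs", stats, time.time() - t0)
    sio.write_map_table(maps, os.path.join(config.out_dir, "maps.tsv"))
    sio.write_map_sam(maps, genome, os.path.join(config.out_dir, "maps.sam"))

    counts = count_maps(maps, scheme, sample=config.sample)
    np.savetxt(
        os.path.join(config.out_dir, "counts.tsv"), counts.counts, fmt="%d", header="count"
    )
    reference = None
    if config.reference_counts:
        ref_vec = np.loadtxt(config.reference_counts, dtype=np.int64)
        reference = BinCounts(counts=ref_vec, sample="reference")
    track = counts_to_track(
        counts,
        scheme,
        genome,
        loess_span=config.loess_span,
        reference=reference,
        match_reference_depth=config.match_reference_depth,
        seed=config.seed,
    )
    sio.write_ratio_track(track, scheme, os.path.join(config.out_dir, "ratio.tsv"))

    segments = cbs_segment(
        track,
        scheme,
        alpha=config.cbs_alpha,
        min_seg_len=config.cbs_min_seg,
        permutations=config.cbs_permutations,
        seed=config.seed,
    )
    fit = quantal_fit(segments, config.quantal_s_bounds, config.quantal_o_bounds)
    sio.write_seg(segments, scheme, config.sample, os.path.join(config.out_dir, "segments.seg"))

    qc = qc_summary(
        track,
        scheme,
        genome,
        total_maps=stats["maps_countable"],
        total_pairs=stats["pairs_in"],
    )
    with open(os.path.join(config.out_dir, "qc.json"), "wt") as fh:
        json.dump({k: (v if v == v else None) for k, v in qc.to_dict().items()}, fh, indent=2)
    log.info("pipeline finished in %.1fs", time.time() - t_start)
    return {
        "genome": genome,
        "scheme": scheme,
        "maps": maps,
        "counts": counts,
        "track": track,
        "segments": segments,
        "quantal": fit,
        "qc": qc,
        "stats": stats,
    }
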