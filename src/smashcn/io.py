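"""Interchange formats: FASTQ pair reading, map tables (TSV + SAM),
ratio-track and segment serialization.

All stage-to-stage interchange is tab-separated text so intermediate
results are inspectable and diffable; SAM is emitted for countable maps
only (one alignment line per map, query_start/length in custom tags).
"""

from __future__ import annotations

import gzip
from typing import Iterator, List, Sequence, Tuple

import pandas as pd
import pysam

from .binning import BinScheme
from .genome import Genome
from .mapping import MapRecord
from .normalization import RatioTrack


def _open_text(path: str):
    return gzip.open(path, "rt") if str(path).endswith(".gz") else open(path, "rt")


def read_fastq_pairs(path1: str, path2: str) -> Iterator[Tuple[str, str, str]]:
    """Yield (pair_id, seq1, seq2) from two mate FASTQ files.

    Raises on desynchronised or truncated mates, naming the record index.
    """
    with _open_text(path1) as f1, _open_text(path2) as f2:
        idx = 0
        while True:
            h1 = f1.readline()
            h2 = f2.readline()
            if not h1 and not h2:
                return
            if bool(h1) != bool(h2):
                raise ValueError(f"mate files desynchronised at record {idx}: one file ended")
            s1, p1, q1 = f1.readline(), f1.readline(), f1.readline()
            s2, p2, q2 = f2.readline(), f2.readline(), f2.readline()
            if not (q1 and q2):
                raise ValueError(f"truncated FASTQ record at index {idx}")
            if not (h1.startswith("@") and h2.startswith("@")):
                raise ValueError(f"malformed FASTQ header at record {idx}")
            id1 = h1[1:].split()[0].rsplit("/", 1)[0]
            id2 = h2[1:].split()[0].rsplit("/", 1)[0]
            if id1 != id2:
                raise ValueError(f"mate ids differ at record {idx}: {id1!r} vs {id2!r}")
            yield id1, s1.strip().upper(), s2.strip().upper()
            idx += 1


def write_map_table(maps: Sequence[MapRecord], path: str) -> None:
    df = pd.DataFrame(
        [
            (m.read_pair_id, m.mate, m.query_start, m.chromosome, m.position, m.strand, m.length)
            for m in maps
        ],
        columns=["read_pair_id", "mate", "query_start", "chrom", "position", "strand", "length"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_map_table(path: str) -> List[MapRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        MapRecord(
            chromosome=str(r.chrom),
            position=int(r.position),
            strand=str(r.strand),
            length=int(r.length),
            read_pair_id=str(r.read_pair_id),
            query_start=int(r.query_start),
            mate=int(r.mate),
        )
        for r in df.itertuples(index=False)
    ]


def write_map_sam(maps: Sequence[MapRecord], genome: Genome, path: str) -> None:
    """One alignment line per countable map.

    The aligned segment is the matched reference interval (CIGAR <len>M);
    tags: ZS = query start of the match in its read, ZM = mate (1/2).
    Positions are converted to SAM's 1-based convention by pysam.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": n, "LN": genome.length(n)} for n in genome.names],
    }
    ref_id = {n: i for i, n in enumerate(genome.names)}
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for m in maps:
            a = pysam.AlignedSegment(out.header)
            a.query_name = m.read_pair_id or "map"
            seq = genome.sequences[m.chromosome][m.position : m.position + m.length]
            a.query_sequence = seq
            a.flag = 16 if m.strand == "-" else 0
            a.reference_id = ref_id[m.chromosome]
            a.reference_start = m.position
            a.mapping_quality = 60
            a.cigarstring = f"{m.length}M"
            a.set_tag("ZS", m.query_start)
            a.set_tag("ZM", m.mate)
            out.write(a)


def write_ratio_track(track: RatioTrack, scheme: BinScheme, path: str) -> None:
    track.to_frame(scheme).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_ratio_track(path: str) -> RatioTrack:
    df = pd.read_csv(path, sep="\t")
    stage = str(df["stage"].iloc[0])
    return RatioTrack(values=df["value"].to_numpy(), stage=stage)


def write_seg(segments, scheme: BinScheme, sample: str, path: str) -> None:
    """SEG-format text (sample, chrom, start, end, n_bins, seg mean)."""
    from .segmentation import segments_to_frame

    df = segments_to_frame(segments, scheme)
    with open(path, "wt") as fh:
        fh.write("ID\tchrom\tloc.start\tloc.end\tnum.mark\tseg.mean\tinteger.cn\n")
        for r in df.itertuples(index=False):
            cn = "" if r.integer_cn is None else int(r.integer_cn)
            fh.write(
                f"{sample}\t{r.chrom}\t{r.start + 1}\t{r.end}\t{r.n_bins}\t{r.mean_ratio:.6g}\t{cn}\n"
            )
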