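"""Reference genome container and FASTA input.

A :class:`Genome` is an ordered mapping of chromosome name to an uppercase
nucleotide string, plus a sex-class label (autosome / X / Y) per chromosome
that downstream normalization and QC statistics rely on.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Dict, Iterator, Tuple

from Bio import SeqIO

VALID_BASES = frozenset("ACGTN")

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGTN string."""
    return seq.translate(_COMP)[::-1]


def infer_sex_class(name: str) -> str:
    """Classify a chromosome name as 'autosome', 'X' or 'Y'.

    Recognises 'X'/'chrX'/'Y'/'chrY' (case-insensitive); everything else is
    an autosome.
    """
    core = name[3:] if name.lower().startswith("chr") else name
    if core.upper() == "X":
        return "X"
    if core.upper() == "Y":
        return "Y"
    return "autosome"


@dataclass
class Genome:
    """Ordered chromosome sequences with sex-class labels.

    Parameters
    ----------
    sequences
        Ordered mapping chromosome name -> uppercase ACGTN string.
    sex_class
        Mapping chromosome name -> one of {'autosome', 'X', 'Y'}.  Inferred
        from names when omitted.
    """

    sequences: Dict[str, str]
    sex_class: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("genome has no chromosomes")
        for name, seq in self.sequences.items():
            seq = seq.upper()
            self.sequences[name] = seq
            bad = set(seq) - VALID_BASES
            if bad:
                pos = next(i for i, c in enumerate(seq) if c in bad)
                raise ValueError(
                    f"invalid base {seq[pos]!r} in chromosome {name!r} at position {pos}"
                )
        if sum(len(s) for s in self.sequences.values()) == 0:
            raise ValueError("genome has zero total length")
        for name in self.sequences:
            self.sex_class.setdefault(name, infer_sex_class(name))

    @property
    def names(self) -> Tuple[str, ...]:
        return tuple(self.sequences)

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def length(self, name: str) -> int:
        return len(self.sequences[name])

    def autosomes(self) -> Tuple[str, ...]:
        return tuple(n for n in self.names if self.sex_class[n] == "autosome")

    def items(self) -> Iterator[Tuple[str, str]]:
        return iter(self.sequences.items())


def read_fasta(path: str) -> Genome:
    """Read a (possibly gzipped) multi-record FASTA into a Genome.

    Lowercase bases are folded to uppercase; wrapped lines are joined.
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    sequences: Dict[str, str] = {}
    with opener(path, "rt") as fh:
        first = fh.read(1)
        if first == "":
            raise ValueError(f"empty FASTA file: {path}")
        if first != ">":
            raise ValueError(f"malformed FASTA (line 1 does not start with '>'): {path}")
        fh.seek(0)
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in sequences:
                raise ValueError(f"duplicate FASTA record name {rec.id!r}")
            sequences[rec.id] = str(rec.seq).upper()
    return Genome(sequences)


def write_fasta(genome: Genome, path: str, width: int = 70) -> None:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
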