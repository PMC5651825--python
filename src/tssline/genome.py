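"""Circular genome sequences with strand-aware CDS annotation.

Coordinates are 1-based inclusive throughout the public API (GFF3
convention).  A transcription start site (TSS) position is the first
transcribed base (+1).  Offsets relative to a TSS or a start codon skip
zero: offset -1 is the base immediately 5' of the reference base, offset
+1 is the reference base itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

VALID_BASES = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Gene:
    """A CDS feature on a circular genome.

    ``start <= end`` always; for minus-strand genes the start codon sits at
    the ``end`` coordinate and transcription proceeds leftwards.
    """

    id: str
    start: int
    end: int
    strand: str  # '+' or '-'

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid interval {self.start}..{self.end}")

    @property
    def start_codon(self) -> int:
        """Genomic position of the first base of the start codon."""
        return self.start if self.strand == "+" else self.end

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass
class GenomeRecord:
    """A (circular) genome sequence plus its gene features."""

    id: str
    seq: str
    features: List[Gene] = field(default_factory=list)
    circular: bool = True

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        bad = set(self.seq) - VALID_BASES
        if bad:
            raise ValueError(f"sequence contains invalid characters: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)

    def wrap(self, position: int) -> int:
        """Map an arbitrary integer onto 1..len under circular wrapping."""
        return (position - 1) % len(self.seq) + 1

    def fetch(self, start: int, end: int, strand: str = "+") -> str:
        """Sequence of the 1-based inclusive interval ``start..end``.

        ``start`` may exceed ``end`` modularly only via circular wrapping:
        callers pass unwrapped coordinates (possibly < 1 or > length) and
        the window is read left to right along the plus strand, then
        reverse-complemented if ``strand`` is '-'.
        """
        if end < start:
            raise ValueError(f"empty window {start}..{end}")
        n = len(self.seq)
        if not self.circular and (start < 1 or end > n):
            raise ValueError(f"window {start}..{end} outside linear genome of length {n}")
        idx = [(p - 1) % n for p in range(start, end + 1)]
        out = "".join(self.seq[i] for i in idx)
        return reverse_complement(out) if strand == "-" else out

    def base_at(self, position: int) -> str:
        return self.seq[(position - 1) % len(self.seq)]


def tss_offset_position(tss: int, strand: str, offset: int, genome_length: int) -> int:
    """Genomic position of ``offset`` relative to a TSS (+1 = the TSS base).

    Offsets skip zero; negative offsets are upstream in transcript
    orientation. Wraps circularly.
    """
    if offset == 0:
        raise ValueError("offset 0 is undefined; use -1/+1")
    step = offset - 1 if offset > 0 else offset
    direction = 1 if strand == "+" else -1
    return (tss + direction * step - 1) % genome_length + 1


def read_fasta(path: str | Path) -> GenomeRecord:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    rec = records[0]
    return GenomeRecord(id=rec.id, seq=str(rec.seq))


def write_fasta(genome: GenomeRecord, path: str | Path, width: int = 70) -> None:
    rec = SeqRecord(Seq(genome.seq), id=genome.id, description="")
    with open(path, "w") as fh:
        SeqIO.write([rec], fh, "fasta")
    del width  # Biopython wraps at 60; width retained for API stability


def read_gff3(path: str | Path) -> List[Gene]:
    """Load CDS features (falling back to `gene`) from a GFF3 file."""
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: List[Gene] = []
    featuretypes = set(db.featuretypes())
    ftype = "CDS" if "CDS" in featuretypes else "gene"
    for feat in db.features_of_type(ftype, order_by="start"):
        fid = feat.attributes.get("ID", [feat.id])[0]
        genes.append(Gene(id=fid, start=feat.start, end=feat.end, strand=feat.strand))
    return genes


def write_gff3(genome: GenomeRecord, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {len(genome)}\n")
        for g in sorted(genome.features, key=lambda g: g.start):
            fh.write(
                f"{genome.id}\ttssline\tCDS\t{g.start}\t{g.end}\t.\t{g.strand}\t0\tID={g.id}\n"
            )


def attach_annotation(genome: GenomeRecord, genes: Iterable[Gene]) -> GenomeRecord:
    genome.features = list(genes)
    for g in genome.features:
        if g.end > len(genome):
            raise ValueError(f"feature {g.id} extends past genome end ({g.end} > {len(genome)})")
    return genome
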