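"""Positional classification of called TSSs relative to annotated ORFs.

Five mutually exclusive classes, assigned with precedence P > S > I > A > N:

* **P** (primary): strongest TSS (by TEX+ count) inside a gene's
  upstream/downstream window on the sense strand;
* **S** (secondary): the remaining TSSs in such a window;
* **I** (internal): sense-strand TSS inside an ORF, outside any window;
* **A** (antisense): TSS opposite an ORF;
* **N** (intergenic): everything else.

The window runs from ``upstream`` nt before the start codon to
``downstream`` nt after it, strand-aware, with circular wrapping.  A TSS
falling inside the windows of two genes goes to the gene with the nearer
start codon (ties to the upstream gene).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import pandas as pd

from .genome import Gene
from .tss_detection import TSSRecord

CLASSES = ("P", "S", "I", "A", "N")


@dataclass(frozen=True)
class ClassificationWindows:
    upstream: int = 300
    downstream: int = 100  # a 150 nt variant is also in circulation; overridable
    antisense_flank: int = 0

    def __post_init__(self) -> None:
        if self.upstream < 0 or self.downstream < 0 or self.antisense_flank < 0:
            raise ValueError("window sizes must be non-negative")


def _signed_offset(position: int, gene: Gene, genome_length: int) -> int:
    """Distance from the start codon to ``position`` along the transcription
    direction (negative = upstream), wrapped to (-L/2, L/2]."""
    raw = position - gene.start_codon if gene.strand == "+" else gene.start_codon - position
    half = genome_length // 2
    return (raw + half) % genome_length - half


def classify_tss(
    tss_list: Sequence[TSSRecord],
    annotation: Sequence[Gene],
    genome_length: int,
    windows: ClassificationWindows = ClassificationWindows(),
) -> List[TSSRecord]:
    """Label every TSS in place and return the list.

    UTR length is recorded for P and S TSSs as the strand-aware distance
    from the TSS to the base preceding the start codon (0 = leaderless;
    negative = initiation downstream of the start codon).
    """
    for t in tss_list:
        if not 1 <= t.position <= genome_length:
            raise ValueError(f"TSS position {t.position} outside genome of length {genome_length}")
        t.tss_class = None  # re-entrant: clear labels from any earlier run
        t.gene = None
        t.utr_length = None

    # 1. window membership and gene assignment (nearest start codon)
    per_gene: Dict[str, List[TSSRecord]] = {}
    assigned_offset: Dict[int, int] = {}
    for idx, t in enumerate(tss_list):
        best: Optional[Gene] = None
        best_off: Optional[int] = None
        for g in annotation:
            if g.strand != t.strand:
                continue
            off = _signed_offset(t.position, g, genome_length)
            if -windows.upstream <= off <= windows.downstream:
                if best is None or abs(off) < abs(best_off) or (
                        abs(off) == abs(best_off) and off > best_off):  # tie -> upstream gene
                    best, best_off = g, off
        if best is not None:
            t.gene = best.id
            assigned_offset[idx] = best_off
            per_gene.setdefault(best.id, []).append(t)

    # 2. within each gene the highest TEX+ count wins P; ties to the most
    #    upstream candidate (strand-aware)
    for gid, cands in per_gene.items():
        def upstream_key(t: TSSRecord) -> int:
            return t.position if t.strand == "+" else -t.position
        primary = max(cands, key=lambda t: (t.tex_plus_count, -upstream_key(t)))
        for t in cands:
            t.tss_class = "P" if t is primary else "S"

    # 3. remaining TSSs: internal / antisense / intergenic
    for idx, t in enumerate(tss_list):
        if t.tss_class in ("P", "S"):
            start_codon_off = assigned_offset[idx]
            t.utr_length = -start_codon_off
            continue
        t.gene = None
        sense_hit = any(g.strand == t.strand and g.contains(t.position) for g in annotation)
        if sense_hit:
            t.tss_class = "I"
            continue
        anti_hit = any(
            g.strand != t.strand and
            g.start - windows.antisense_flank <= t.position <= g.end + windows.antisense_flank
            for g in annotation
        )
        t.tss_class = "A" if anti_hit else "N"
    return list(tss_list)


def summarize_classes(tss_list: Sequence[TSSRecord], annotation: Sequence[Gene]) -> dict:
    """Class counts plus gene-level primary-TSS coverage."""
    counts = {c: 0 for c in CLASSES}
    genes_with_primary = set()
    for t in tss_list:
        if t.tss_class not in counts:
            raise RuntimeError(f"unlabelled or unknown class on TSS at {t.position}")
        counts[t.tss_class] += 1
        if t.tss_class == "P":
            genes_with_primary.add(t.gene)
    n_genes = len(annotation)
    return {
        "class_counts": counts,
        "total_tss": sum(counts.values()),
        "genes_with_primary": len(genes_with_primary),
        "fraction_genes_with_primary": (len(genes_with_primary) / n_genes) if n_genes else 0.0,
    }


def classification_table(tss_list: Sequence[TSSRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "position": t.position,
        "strand": t.strand,
        "class": t.tss_class,
        "gene": t.gene or "",
        "utr_length": t.utr_length if t.utr_length is not None else "",
    } for t in tss_list], columns=["position", "strand", "class", "gene", "utr_length"])
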