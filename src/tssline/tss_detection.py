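"""TSS calling from paired TEX+/TEX- 5'-end count profiles.

The exonuclease in the TEX+ library degrades 5'-monophosphorylated
(processed) transcripts, so a genuine transcription start site shows a
5'-end signal enriched in TEX+ relative to TEX-.  A position is called
when its raw TEX+ count clears ``min_count`` and its library-size
normalized TEX+/TEX- ratio (with pseudocount) clears ``min_enrichment``;
nearby candidates on one strand are merged into a single site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .profiles import EndCountProfile, read_bedgraph


@dataclass(frozen=True)
class DetectionParams:
    """Thresholds for TSS calling."""

    min_count: int = 10          # raw TEX+ reads required at a candidate
    min_enrichment: float = 2.0  # CPM-normalized TEX+/TEX- fold change
    cluster_window: int = 5      # nt; same-strand candidates this close merge
    pseudocount: float = 1.0     # added to both normalized counts

    def __post_init__(self) -> None:
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")
        if self.min_enrichment <= 0:
            raise ValueError("min_enrichment must be positive")
        if self.cluster_window < 0:
            raise ValueError("cluster_window must be >= 0")


@dataclass
class TSSRecord:
    """One called transcription start site."""

    position: int  # 1-based
    strand: str
    tex_plus_count: int
    tex_minus_count: int
    enrichment: float
    tss_class: Optional[str] = None  # P, S, I, A or N (set by classification)
    gene: Optional[str] = None
    utr_length: Optional[int] = None


def load_end_counts(paths: Dict[str, str | Path], genome_length: int,
                    library: str) -> Dict[str, EndCountProfile]:
    """Load a strand-keyed pair of bedGraph files ({'+': path, '-': path})."""
    return {
        strand: read_bedgraph(p, genome_length, library=library, strand=strand)
        for strand, p in paths.items()
    }


def normalize_pair(plus: EndCountProfile, minus: EndCountProfile) -> Tuple[EndCountProfile, EndCountProfile]:
    """Scale both profiles to counts-per-million of their library totals.

    Raw counts are retained; the CPM vector is attached as ``normalized``.
    """
    if len(plus) != len(minus):
        raise ValueError("profiles cover genomes of different lengths")
    for prof in (plus, minus):
        total = prof.library_total
        if total == 0:
            raise ValueError(f"library {prof.library} ({prof.strand}) has zero total counts")
        prof.normalized = prof.counts * (1e6 / total)
    return plus, minus


def call_tss(
    tex_plus: Dict[str, EndCountProfile],
    tex_minus: Dict[str, EndCountProfile],
    params: DetectionParams = DetectionParams(),
    circular: bool = True,
) -> List[TSSRecord]:
    """Call TSSs on both strands from TEX+/TEX- profile pairs.

    Library totals are computed over both strands of each library so the
    two strands share one normalization factor.
    """
    plus_total = sum(p.library_total for p in tex_plus.values())
    minus_total = sum(p.library_total for p in tex_minus.values())
    if plus_total == 0 or minus_total == 0:
        raise ValueError("a library has zero total counts; cannot normalize")

    records: List[TSSRecord] = []
    for strand in sorted(tex_plus):
        p, m = tex_plus[strand], tex_minus[strand]
        if len(p) != len(m):
            raise ValueError("TEX+/TEX- profiles differ in length")
        norm_p = p.counts * (1e6 / plus_total)
        norm_m = m.counts * (1e6 / minus_total)
        enrich = (norm_p + params.pseudocount) / (norm_m + params.pseudocount)
        candidate = (p.counts >= params.min_count) & (enrich >= params.min_enrichment)
        positions = np.flatnonzero(candidate) + 1
        for cluster in _cluster_positions(positions, params.cluster_window, len(p), circular):
            best = _pick_representative(cluster, p.counts, strand)
            records.append(TSSRecord(
                position=int(best),
                strand=strand,
                tex_plus_count=int(p.counts[best - 1]),
                tex_minus_count=int(m.counts[best - 1]),
                enrichment=float(enrich[best - 1]),
            ))
    records.sort(key=lambda r: (r.position, r.strand))
    return records


def _cluster_positions(positions: np.ndarray, window: int, genome_length: int,
                       circular: bool) -> List[List[int]]:
    """Group sorted positions whose neighbours are within ``window`` nt.

    On a circular genome the first and last clusters merge if they are
    wrap-adjacent.
    """
    if len(positions) == 0:
        return []
    clusters: List[List[int]] = [[int(positions[0])]]
    for pos in positions[1:]:
        if pos - clusters[-1][-1] <= window:
            clusters[-1].append(int(pos))
        else:
            clusters.append([int(pos)])
    if circular and len(clusters) > 1:
        wrap_gap = (clusters[0][0] + genome_length) - clusters[-1][-1]
        if wrap_gap <= window:
            clusters[-1].extend(clusters.pop(0))
    return clusters


def _pick_representative(cluster: List[int], counts: np.ndarray, strand: str) -> int:
    """Highest-count position; ties broken toward the 5' (upstream) end."""
    best_count = max(counts[p - 1] for p in cluster)
    tied = [p for p in cluster if counts[p - 1] == best_count]
    return min(tied) if strand == "+" else max(tied)


def tss_table(records: List[TSSRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "position": r.position,
        "strand": r.strand,
        "tex_plus_count": r.tex_plus_count,
        "tex_minus_count": r.tex_minus_count,
        "enrichment": r.enrichment,
        "class": r.tss_class or "",
        "gene": r.gene or "",
        "utr_length": r.utr_length if r.utr_length is not None else "",
    } for r in records], columns=["position", "strand", "tex_plus_count",
                                  "tex_minus_count", "enrichment", "class",
                                  "gene", "utr_length"])


def write_tss_tsv(records: List[TSSRecord], path: str | Path) -> None:
    tss_table(records).to_csv(path, sep="\t", index=False)


def write_tss_bed(records: List[TSSRecord], path: str | Path, name: str = "TSS") -> None:
    """BED6 output; score = TEX+ count capped at 1000 (BED convention)."""
    with open(path, "w") as fh:
        for i, r in enumerate(records):
            score = min(r.tex_plus_count, 1000)
            fh.write(f"genome\t{r.position - 1}\t{r.position}\t{name}_{i}\t{score}\t{r.strand}\n")
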