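"""5'UTR length statistics and ribosome-binding-site (Shine-Dalgarno) search.

The 5'UTR of a primary TSS is the stretch between the TSS and the base
preceding the start codon (length 0 = leaderless transcript).  The RBS
is sought as a GGAGR-like purine-rich word in the -17..+3 window around
the start codon; the spacer is the distance between the last RBS base
and the base before the start codon, which clusters at 5-10 nt in most
bacterial genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .genome import Gene, GenomeRecord, tss_offset_position
from .motifs import MotifModel, encode
from .tss_detection import TSSRecord

PURINES = frozenset("AG")


@dataclass
class UTRStats:
    """Summary of primary-TSS 5'UTR lengths (10-nt histogram bins)."""

    lengths: List[int]
    histogram: Dict[str, int]       # "0-9", "10-19", ...
    median: float
    fraction_lt_100: float
    long_utrs: List[Tuple[int, str, int]]  # (tss position, gene, length) > 100 nt
    negative: List[Tuple[int, str, int]] = field(default_factory=list)  # flagged

    @property
    def n(self) -> int:
        return len(self.lengths)


def compute_utrs(primary_tss: Sequence[TSSRecord], annotation: Sequence[Gene]) -> UTRStats:
    """UTR length distribution over primary TSSs.

    Lengths come from the classification step (``utr_length``); TSSs
    labelled P but lying downstream of their start codon have negative
    lengths and are flagged rather than binned.
    """
    gene_by_id = {g.id: g for g in annotation}
    lengths: List[int] = []
    negative: List[Tuple[int, str, int]] = []
    long_utrs: List[Tuple[int, str, int]] = []
    for t in primary_tss:
        if t.gene is None or t.gene not in gene_by_id:
            raise ValueError(f"primary TSS at {t.position} has no linked gene")
        if t.utr_length is None:
            raise ValueError(f"primary TSS at {t.position} lacks a UTR length")
        if t.utr_length < 0:
            negative.append((t.position, t.gene, t.utr_length))
            continue
        lengths.append(t.utr_length)
        if t.utr_length > 100:
            long_utrs.append((t.position, t.gene, t.utr_length))
    histogram: Dict[str, int] = {}
    if lengths:
        top = (max(lengths) // 10) * 10
        for lo in range(0, top + 1, 10):
            histogram[f"{lo}-{lo + 9}"] = 0
        for L in lengths:
            lo = (L // 10) * 10
            histogram[f"{lo}-{lo + 9}"] += 1
    return UTRStats(
        lengths=lengths,
        histogram=histogram,
        median=float(np.median(lengths)) if lengths else float("nan"),
        fraction_lt_100=float(np.mean([L < 100 for L in lengths])) if lengths else 0.0,
        long_utrs=long_utrs,
        negative=negative,
    )


@dataclass
class RBSHit:
    gene: str
    sequence: str
    offset: int      # start-codon-relative offset of the first RBS base
    spacer: int      # nt between RBS end and the base before the start codon
    score: float
    truncated: bool = False


def _degenerate_pwm(consensus: str, match_prob: float = 0.91) -> np.ndarray:
    """Log2-odds matrix for a degenerate consensus (R = A/G, Y = C/T)."""
    table = {"R": "AG", "Y": "CT"}
    w = len(consensus)
    probs = np.full((w, 4), 0.0)
    for k, c in enumerate(consensus):
        allowed = table.get(c, c)
        rest = (1 - match_prob) / (4 - len(allowed))
        probs[k, :] = rest
        for b in allowed:
            probs[k, "ACGT".index(b)] = match_prob / len(allowed)
    return np.log2(probs / 0.25)


def find_rbs(
    genes: Sequence[Gene],
    genome: GenomeRecord,
    utr_lengths: Optional[Dict[str, int]] = None,
    motif: str | MotifModel = "GGAGR",
    window: Tuple[int, int] = (-17, 3),
    score_margin_bits: float = 2.0,
) -> List[RBSHit]:
    """Best RBS match per gene in the start-codon-relative search window.

    The default scorer is a degenerate-consensus PWM for GGAGR with an
    acceptance threshold of (perfect score - ``score_margin_bits``); a
    fitted :class:`MotifModel` may be passed instead.  When the known
    5'UTR is shorter than the window, the window is truncated to the UTR
    and the hit flagged.
    """
    if isinstance(motif, MotifModel):
        pwm = motif.pwm
        width = motif.width
    else:
        pwm = _degenerate_pwm(motif)
        width = len(motif)
    threshold = float(pwm.max(axis=1).sum()) - score_margin_bits

    n = len(genome)
    hits: List[RBSHit] = []
    for g in genes:
        lo, hi = window
        truncated = False
        if utr_lengths is not None and g.id in utr_lengths:
            utr = utr_lengths[g.id]
            if utr < -lo:
                lo = -utr if utr > 0 else -1
                truncated = True
        offsets = [o for o in range(lo, hi + 1) if o != 0]
        if len(offsets) < width:
            continue
        seq = "".join(
            genome.base_at(tss_offset_position(g.start_codon, g.strand, o, n))
            if g.strand == "+" else
            _complement(genome.base_at(tss_offset_position(g.start_codon, g.strand, o, n)))
            for o in offsets
        )
        best_score, best_j = -np.inf, None
        idx = encode(seq)
        for j in range(len(seq) - width + 1):
            s = float(pwm[np.arange(width), idx[j:j + width]].sum())
            if s > best_score:
                best_score, best_j = s, j
        if best_j is None or best_score < threshold:
            continue
        start_off = offsets[best_j]
        end_off = offsets[best_j + width - 1]
        spacer = -end_off - 1  # nt between RBS end and the base before ATG
        hits.append(RBSHit(gene=g.id, sequence=seq[best_j:best_j + width],
                           offset=start_off, spacer=spacer, score=best_score,
                           truncated=truncated))
    return hits


def rbs_spacer_histogram(hits: Sequence[RBSHit]) -> Dict[int, int]:
    out: Dict[int, int] = {}
    for h in hits:
        out[h.spacer] = out.get(h.spacer, 0) + 1
    return dict(sorted(out.items()))


def _complement(base: str) -> str:
    return {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}[base]
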