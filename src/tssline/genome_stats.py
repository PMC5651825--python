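"""Genome-level descriptive statistics and GC-skew replication origin detection.

The cumulative GC skew (G-C)/(G+C), computed in tiling windows around the
circular chromosome, changes sign at the replication origin and terminus
because the leading strand is G-enriched: the cumulative curve attains
its global minimum at the origin and its global maximum at the terminus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
import pandas as pd

from .genome import GenomeRecord


@dataclass
class SkewProfile:
    """Windowed GC skew and its cumulative sum along a genome."""

    window_size: int
    step: int
    midpoints: np.ndarray  # genome position of each window centre (1-based)
    skew: np.ndarray       # (G-C)/(G+C) per window, in [-1, 1]
    cumulative: np.ndarray

    def __len__(self) -> int:
        return len(self.skew)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "midpoint": self.midpoints,
            "skew": self.skew,
            "cumulative": self.cumulative,
        })


def _base_counts(seq: str) -> dict:
    return {b: seq.count(b) for b in "ACGTN"}


def gc_content(genome: GenomeRecord | str) -> float:
    """Fraction (G+C)/(A+C+G+T); N bases excluded from both terms."""
    seq = genome.seq if isinstance(genome, GenomeRecord) else genome.upper()
    if not seq:
        raise ValueError("empty sequence")
    c = _base_counts(seq)
    denom = c["A"] + c["C"] + c["G"] + c["T"]
    if denom == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return (c["G"] + c["C"]) / denom


def coding_density(genome: GenomeRecord) -> float:
    """Fraction of genome bases covered by at least one CDS (union, both strands)."""
    if not genome.features:
        raise ValueError("no annotation present")
    n = len(genome)
    covered = np.zeros(n, dtype=bool)
    for g in genome.features:
        if g.end > n or g.start < 1:
            raise ValueError(f"CDS {g.id} outside genome bounds")
        covered[g.start - 1:g.end] = True
    return covered.sum() / n


def cumulative_gc_skew(genome: GenomeRecord | str, window: int = 1000, step: int = 1000) -> SkewProfile:
    """Per-window (G-C)/(G+C) and its running sum.

    Windows tile from position 1 with the given step; the final window
    wraps circularly. Windows with no G or C get skew 0.
    """
    seq = genome.seq if isinstance(genome, GenomeRecord) else genome.upper()
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    n = len(seq)
    if window > n:
        raise ValueError(f"window {window} exceeds genome length {n}")
    is_g = np.frombuffer(seq.encode(), dtype="S1") == b"G"
    is_c = np.frombuffer(seq.encode(), dtype="S1") == b"C"
    starts = np.arange(0, n, step)
    skew = np.empty(len(starts))
    mid = np.empty(len(starts), dtype=np.int64)
    for i, s in enumerate(starts):
        idx = np.arange(s, s + window) % n  # circular wrap for the final window
        g = int(is_g[idx].sum())
        c = int(is_c[idx].sum())
        skew[i] = 0.0 if g + c == 0 else (g - c) / (g + c)
        mid[i] = (s + window // 2) % n + 1
    return SkewProfile(window_size=window, step=step, midpoints=mid,
                       skew=skew, cumulative=np.cumsum(skew))


def locate_origin_terminus(profile: SkewProfile) -> Tuple[int, int]:
    """(origin, terminus) positions from cumulative-skew extrema.

    Origin = window midpoint of the global cumulative minimum (leading
    strand ahead of the origin is G-rich, so the cumulative curve rises
    after it); terminus = midpoint of the global maximum.
    """
    if np.allclose(profile.skew, profile.skew[0]):
        raise ValueError("skew profile is constant; origin/terminus undefined")
    origin = int(profile.midpoints[int(np.argmin(profile.cumulative))])
    terminus = int(profile.midpoints[int(np.argmax(profile.cumulative))])
    return origin, terminus


def genome_summary(genome: GenomeRecord, window: int = 1000, step: int = 1000) -> dict:
    """Table-style summary: size, GC%, coding density, gene count, ori/ter."""
    summary = {
        "genome_size_bp": len(genome),
        "gc_fraction": gc_content(genome),
        "n_genes": len(genome.features),
    }
    if genome.features:
        summary["coding_density"] = coding_density(genome)
    try:
        ori, ter = locate_origin_terminus(cumulative_gc_skew(genome, window, step))
        summary["origin"] = ori
        summary["terminus"] = ter
    except ValueError:
        summary["origin"] = summary["terminus"] = None
    return summary
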