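"""Per-position 5'-end count profiles and their bedGraph serialization.

A dRNA-Seq library yields, for every genome position and strand, the
number of reads whose 5' end maps exactly there.  Profiles are stored as
dense integer vectors (index 0 = genome position 1).  bedGraph files use
0-based half-open intervals, one per run of equal non-zero counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class EndCountProfile:
    """5'-end counts for one library on one strand."""

    library: str
    strand: str  # '+' or '-'
    counts: np.ndarray  # shape (genome_length,), non-negative ints
    normalized: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise ValueError("counts must be a 1-D vector")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def library_total(self) -> int:
        return int(self.counts.sum())

    def __len__(self) -> int:
        return len(self.counts)


STRAND_TOKEN = {"+": "fwd", "-": "rev"}
TOKEN_STRAND = {v: k for k, v in STRAND_TOKEN.items()}


def profile_filename(library: str, strand: str) -> str:
    return f"{library}_{STRAND_TOKEN[strand]}.bedgraph"


def write_bedgraph(profile: EndCountProfile, path: str | Path) -> None:
    """Write runs of equal non-zero counts as 0-based half-open intervals."""
    counts = profile.counts
    with open(path, "w") as fh:
        fh.write(f"track type=bedGraph name={profile.library}_{STRAND_TOKEN[profile.strand]}\n")
        n = len(counts)
        # boundaries of runs of equal value
        change = np.flatnonzero(np.diff(counts)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [n]))
        for s, e in zip(starts, ends):
            v = counts[s]
            if v != 0:
                fh.write(f"genome\t{s}\t{e}\t{int(v)}\n")


def read_bedgraph(path: str | Path, genome_length: int,
                  library: str | None = None, strand: str | None = None) -> EndCountProfile:
    """Load a bedGraph into a dense per-position vector.

    Positions absent from the file are zero. Raises on malformed lines
    (with the line number) and on negative values.
    """
    path = Path(path)
    if library is None or strand is None:
        stem = path.stem
        if "_" in stem:
            lib_part, tok = stem.rsplit("_", 1)
            library = library or lib_part
            strand = strand or TOKEN_STRAND.get(tok, "+")
        else:
            library = library or stem
            strand = strand or "+"
    counts = np.zeros(genome_length, dtype=np.int64)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 tab-separated fields, got {len(parts)}")
            try:
                start, end, value = int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparsable coordinates/value") from exc
            if value < 0:
                raise ValueError(f"{path}:{lineno}: negative count {value}")
            if start < 0 or end > genome_length or end <= start:
                raise ValueError(f"{path}:{lineno}: interval [{start},{end}) outside genome")
            counts[start:end] += int(value)
    return EndCountProfile(library=library, strand=strand, counts=counts)


def profile_to_frame(profile: EndCountProfile) -> pd.DataFrame:
    """Non-zero positions as a tidy table (1-based positions)."""
    pos = np.flatnonzero(profile.counts) + 1
    return pd.DataFrame({
        "position": pos,
        "strand": profile.strand,
        "count": profile.counts[pos - 1],
    })
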