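"""Promoter motif discovery by expectation-maximization (ZOOPS model).

Each input window (e.g. the 20 nt upstream of a TSS) is assumed to carry
zero or one occurrence of an unknown ungapped motif of fixed width; all
other positions follow a background base distribution.  EM alternates
between posterior site assignment (E-step) and position-frequency-matrix
re-estimation (M-step) until the log-likelihood stabilizes, restarted
from several random seeds.  Significance of the recovered motif's total
information content is assessed by a within-window base-shuffling
permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .genome import GenomeRecord, tss_offset_position
from .tss_detection import TSSRecord

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


@dataclass
class MotifModel:
    """A discovered ungapped motif: counts, log-odds and site assignments."""

    width: int
    pfm: np.ndarray           # (width, 4) pseudocounted base counts
    background: np.ndarray    # (4,) base frequencies
    sites: List[Tuple[int, int]] = field(default_factory=list)  # (sequence index, offset)
    occupancy: float = 0.0    # fraction of sequences with occurrence posterior > 0.5
    log_likelihood: float = float("-inf")
    p_value: Optional[float] = None

    @property
    def probabilities(self) -> np.ndarray:
        return self.pfm / self.pfm.sum(axis=1, keepdims=True)

    @property
    def pwm(self) -> np.ndarray:
        """Per-position log2 odds versus background."""
        return np.log2(self.probabilities / self.background[None, :])

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.probabilities.argmax(axis=1))

    @property
    def information_content(self) -> np.ndarray:
        """Per-position relative entropy vs background, in bits."""
        p = self.probabilities
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, p * np.log2(p / self.background[None, :]), 0.0)
        return terms.sum(axis=1)

    @property
    def total_information(self) -> float:
        return float(self.information_content.sum())

    def score(self, sequence: str) -> float:
        """Log2-odds PWM score of a sequence of exactly ``width`` bases."""
        if len(sequence) != self.width:
            raise ValueError("sequence length must equal motif width")
        idx = encode(sequence)
        return float(self.pwm[np.arange(self.width), idx].sum())

    def to_meme_text(self, name: str = "MOTIF_1") -> str:
        """Minimal MEME text format (consumable by logo renderers)."""
        bg = " ".join(f"{b} {f:.5f}" for b, f in zip(ALPHABET, self.background))
        lines = [
            "MEME version 4", "", "ALPHABET= ACGT", "", "strands: +", "",
            "Background letter frequencies", bg, "",
            f"MOTIF {name}",
            f"letter-probability matrix: alength= 4 w= {self.width} nsites= {len(self.sites)}",
        ]
        for row in self.probabilities:
            lines.append(" ".join(f"{v:.6f}" for v in row))
        return "\n".join(lines) + "\n"


def encode(sequence: str) -> np.ndarray:
    try:
        return np.array([_BASE_INDEX[b] for b in sequence.upper()], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"non-ACGT base in sequence: {exc}") from exc


def extract_window(tss: TSSRecord, genome: GenomeRecord,
                   from_offset: int, to_offset: int) -> str:
    """Sense-strand sequence of TSS-relative offsets ``from_offset..to_offset``.

    Offsets skip 0 (-1 is the base immediately 5' of the TSS, +1 the TSS
    itself); the window is reverse-complemented for minus-strand TSSs and
    wraps circularly.
    """
    if from_offset > to_offset:
        raise ValueError("from_offset must not exceed to_offset")
    n = len(genome)
    offsets = [o for o in range(from_offset, to_offset + 1) if o != 0]
    if not offsets:
        raise ValueError("zero-length window")
    return "".join(
        genome.base_at(tss_offset_position(tss.position, tss.strand, o, n))
        if tss.strand == "+" else
        _complement(genome.base_at(tss_offset_position(tss.position, tss.strand, o, n)))
        for o in offsets
    )


def _complement(base: str) -> str:
    return {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}[base]


def _window_scores(X: np.ndarray, log_ratio: np.ndarray, width: int) -> np.ndarray:
    """log(P(window|motif)/P(window|bg)) for every offset; shape (n, m-w+1)."""
    n, m = X.shape
    n_off = m - width + 1
    S = np.zeros((n, n_off))
    for k in range(width):
        S += log_ratio[k, X[:, k:k + n_off]]
    return S


def _em_run(X: np.ndarray, width: int, background: np.ndarray,
            rng: np.random.Generator, pseudocount: float, gamma0: float,
            tol: float, max_iter: int,
            init_probs: Optional[np.ndarray] = None,
            ) -> Tuple[np.ndarray, float, float, np.ndarray]:
    """One EM run; returns (pfm, gamma, log-likelihood, posteriors)."""
    n, m = X.shape
    n_off = m - width + 1
    if init_probs is None:
        # seed the PFM from a random window, smoothed toward background
        i = rng.integers(n)
        j = rng.integers(n_off)
        seed_probs = np.full((width, 4), 0.15)
        seed_probs[np.arange(width), X[i, j:j + width]] = 0.55
        probs = seed_probs
    else:
        probs = init_probs
    gamma = gamma0
    prev_ll = -np.inf
    Z = np.zeros((n, n_off))
    for _ in range(max_iter):
        log_ratio = np.log(probs / background[None, :])
        S = _window_scores(X, log_ratio, width)
        # per-sequence mixture over "no site" and each offset
        site_w = (gamma / n_off) * np.exp(S - S.max(axis=1, keepdims=True))
        scale = S.max(axis=1)
        none_w = (1 - gamma) * np.exp(-scale)
        denom = none_w + site_w.sum(axis=1)
        Z = site_w / denom[:, None]
        q = 1.0 - none_w / denom  # occurrence posterior per sequence
        ll = float(np.sum(np.log(denom) + scale))  # + constant bg term
        # M-step
        counts = np.full((width, 4), pseudocount)
        for k in range(width):
            for b in range(4):
                counts[k, b] += Z[:, :][(X[:, k:k + n_off] == b)].sum()
        probs = counts / counts.sum(axis=1, keepdims=True)
        gamma = float(np.clip(q.mean(), 1e-6, 1 - 1e-6))
        if abs(ll - prev_ll) < tol:
            prev_ll = ll
            break
        prev_ll = ll
    counts = np.full((width, 4), pseudocount)
    for k in range(width):
        for b in range(4):
            counts[k, b] += Z[:, :][(X[:, k:k + n_off] == b)].sum()
    return counts, gamma, prev_ll, Z


def discover_motif(
    windows: Sequence[str],
    width: int = 6,
    n_restarts: int = 20,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 200,
    pseudocount: float = 0.25,
    occurrence_prior: float = 0.8,
    background: Optional[np.ndarray] = None,
) -> MotifModel:
    """ZOOPS EM motif discovery over equal-length sequence windows.

    The best of ``n_restarts`` randomly-seeded runs (by final likelihood)
    is returned.  A site is reported for a sequence only when a single
    offset carries the majority (> 0.5) of its posterior mass, i.e. the
    occurrence is both present and localized; sequences where the mass is
    split between competing offsets get no site.  ``occupancy`` tracks
    presence (total occurrence posterior > 0.5) regardless of
    localization.
    """
    if width < 4:
        raise ValueError("width must be at least 4")
    lengths = {len(w) for w in windows}
    if len(lengths) != 1:
        raise ValueError("all windows must have equal length")
    (m,) = lengths
    if m < width:
        raise ValueError(f"width {width} exceeds window length {m}")
    X = np.stack([encode(w) for w in windows])
    if background is None:
        background = np.bincount(X.ravel(), minlength=4).astype(float)
        background = np.maximum(background, 1.0)
        background /= background.sum()

    rng = np.random.default_rng(seed)
    best: Optional[Tuple[np.ndarray, float, float, np.ndarray]] = None
    for _ in range(max(n_restarts, 1)):
        result = _em_run(X, width, background, rng, pseudocount,
                         occurrence_prior, tol, max_iter)
        if best is None or result[2] > best[2]:
            best = result
    # phase polish: EM has a registration ambiguity (the motif can lock on
    # one column off the true frame); re-seed from column-shifted variants
    # of the best model and keep the highest-likelihood outcome
    best_probs = best[0] / best[0].sum(axis=1, keepdims=True)
    for shift in (-2, -1, 1, 2):
        shifted = np.tile(background, (width, 1)).astype(float)
        if shift > 0:
            shifted[:width - shift] = best_probs[shift:]
        else:
            shifted[-shift:] = best_probs[:width + shift]
        result = _em_run(X, width, background, rng, pseudocount,
                         occurrence_prior, tol, max_iter, init_probs=shifted)
        if result[2] > best[2]:
            best = result
    pfm, gamma, ll, Z = best
    q = Z.sum(axis=1)
    sites = [(int(i), int(Z[i].argmax())) for i in np.flatnonzero(Z.max(axis=1) > 0.5)]
    return MotifModel(width=width, pfm=pfm, background=background, sites=sites,
                      occupancy=float(np.mean(q > 0.5)), log_likelihood=ll)


def motif_significance(
    motif: MotifModel,
    windows: Sequence[str],
    n_permutations: int = 199,
    seed: int = 0,
    n_restarts: int = 3,
    max_iter: int = 60,
    tol: float = 1e-4,
) -> float:
    """Permutation p-value for the motif's total information content.

    Each permutation shuffles the bases *within* every window
    independently (preserving per-window composition), re-runs discovery
    with identical settings on both observed and shuffled data, and
    compares total information content.  p = (1 + #{perm >= obs}) / (1 + N).
    """
    if n_permutations < 99:
        raise ValueError("use at least 99 permutations")
    rng = np.random.default_rng(seed)

    def rediscover(seqs: Sequence[str], s: int) -> float:
        mod = discover_motif(seqs, width=motif.width, n_restarts=n_restarts,
                             seed=s, tol=tol, max_iter=max_iter,
                             background=motif.background)
        return mod.total_information

    observed = rediscover(windows, int(rng.integers(2**31)))
    exceed = 0
    chars = [np.frombuffer(w.encode(), dtype="S1") for w in windows]
    for _ in range(n_permutations):
        shuffled = ["".join(rng.permutation(c).tobytes().decode()) for c in chars]
        if rediscover(shuffled, int(rng.integers(2**31))) >= observed:
            exceed += 1
    return (1 + exceed) / (1 + n_permutations)


def assign_minus35_and_spacers(
    minus10: MotifModel,
    minus35: MotifModel,
    n_tss: int,
    minus10_window_start: int = -20,
    minus35_window_start: int = -50,
) -> dict:
    """Per-TSS promoter architecture and the -35/-10 spacer histogram.

    Site offsets within each search window are mapped back to
    TSS-relative coordinates; spacer = (-10 start) - (-35 end) - 1.
    Overlapping assignments yield negative spacers and are flagged.
    """
    m10 = {i: off for i, off in minus10.sites}
    m35 = {i: off for i, off in minus35.sites}
    spacers: Dict[int, int] = {}
    architecture = {"both": 0, "minus10_only": 0, "minus35_only": 0, "neither": 0}
    flagged_overlaps = 0
    for i in range(n_tss):
        has10, has35 = i in m10, i in m35
        if has10 and has35:
            architecture["both"] += 1
            ten_start = minus10_window_start + m10[i]
            thirtyfive_end = minus35_window_start + m35[i] + minus35.width - 1
            spacer = ten_start - thirtyfive_end - 1
            spacers[i] = spacer
            if spacer < 0:
                flagged_overlaps += 1
        elif has10:
            architecture["minus10_only"] += 1
        elif has35:
            architecture["minus35_only"] += 1
        else:
            architecture["neither"] += 1
    hist: Dict[int, int] = {}
    for s in spacers.values():
        hist[s] = hist.get(s, 0) + 1
    return {
        "spacers": spacers,
        "spacer_histogram": dict(sorted(hist.items())),
        "architecture": architecture,
        "overlapping_sites": flagged_overlaps,
        "fraction_minus10": (architecture["both"] + architecture["minus10_only"]) / n_tss if n_tss else 0.0,
        "fraction_both": architecture["both"] / n_tss if n_tss else 0.0,
    }


def composition_at_tss(tss_list: Sequence[TSSRecord], genome: GenomeRecord,
                       from_offset: int = -2, to_offset: int = 2) -> dict:
    """Base frequencies at TSS-relative offsets, with the -1 pyrimidine and
    +1 purine fractions that characterize bacterial initiation sites."""
    offsets = [o for o in range(from_offset, to_offset + 1) if o != 0]
    freqs: Dict[int, Dict[str, float]] = {}
    counts = {o: {b: 0 for b in ALPHABET} for o in offsets}
    for t in tss_list:
        window = extract_window(t, genome, from_offset, to_offset)
        for o, b in zip(offsets, window):
            if b in counts[o]:
                counts[o][b] += 1
    for o in offsets:
        total = sum(counts[o].values())
        freqs[o] = {b: (counts[o][b] / total if total else 0.0) for b in ALPHABET}
    return {
        "frequencies": freqs,
        "pyrimidine_minus1": freqs[-1]["C"] + freqs[-1]["T"] if -1 in freqs else None,
        "purine_plus1": freqs[1]["A"] + freqs[1]["G"] if 1 in freqs else None,
    }
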