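"""Pan-genome gene-family classification and neighbour-joining tree.

Proteins from several genomes are compared all-vs-all by local alignment
(BLOSUM62, affine gaps), the resulting similarity graph is clustered
with the Markov cluster (MCL) algorithm into gene families, and each
family is categorized by its genome span: *core* (all genomes),
*dispensable* (two or more, but not all) or *unique* (one genome).  A
pan-genome tree is built by neighbour joining on Jaccard distances over
family presence/absence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices
from scipy.sparse.csgraph import connected_components
from scipy.sparse import csr_matrix

# Karlin-Altschul parameters of gapped BLOSUM62 (open 11 / extend 1)
KA_LAMBDA = 0.267
KA_K = 0.041


@dataclass
class SimilarityGraph:
    """Undirected protein similarity graph over genome-qualified ids."""

    nodes: List[str]
    edges: List[Tuple[int, int, float]]  # (i, j, raw alignment score), i < j
    score_min: float = 50.0
    evalue_max: float = 1e-10

    @property
    def n(self) -> int:
        return len(self.nodes)


@dataclass
class PanGenomeResult:
    families: List[List[str]]                  # protein ids per family
    category: List[str]                        # per family
    genome_of: Dict[str, str]
    genomes: List[str]
    distance_matrix: Optional[np.ndarray] = None
    tree_newick: Optional[str] = None
    negative_branches_clamped: int = 0

    def family_counts(self) -> Dict[str, int]:
        out = {"core": 0, "dispensable": 0, "unique": 0}
        for c in self.category:
            out[c] += 1
        return out

    def gene_counts(self) -> Dict[str, int]:
        out = {"core": 0, "dispensable": 0, "unique": 0}
        for fam, c in zip(self.families, self.category):
            out[c] += len(fam)
        return out

    def per_genome_gene_counts(self) -> Dict[str, Dict[str, int]]:
        out = {g: {"core": 0, "dispensable": 0, "unique": 0} for g in self.genomes}
        for fam, c in zip(self.families, self.category):
            for pid in fam:
                out[self.genome_of[pid]][c] += 1
        return out


def read_proteomes(directory: str | Path) -> Dict[str, List[Tuple[str, str]]]:
    """Load one protein FASTA per genome (``<genome>.faa``); ids are taken
    as-is when already ``<genome>|<protein>``, otherwise qualified."""
    directory = Path(directory)
    proteomes: Dict[str, List[Tuple[str, str]]] = {}
    for path in sorted(directory.glob("*.faa")) + sorted(directory.glob("*.fasta")):
        genome = path.stem
        records = []
        for rec in SeqIO.parse(str(path), "fasta"):
            pid = rec.id if rec.id.startswith(f"{genome}|") else f"{genome}|{rec.id}"
            records.append((pid, str(rec.seq)))
        proteomes[genome] = records
    if not proteomes:
        raise ValueError(f"no proteome FASTA files found in {directory}")
    return proteomes


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def evalue_proxy(score: float, len_a: int, len_b: int) -> float:
    """Karlin-Altschul style E-value with fixed gapped-BLOSUM62 parameters
    and search space = query length x subject length."""
    return KA_K * len_a * len_b * math.exp(-KA_LAMBDA * score)


def score_pairs(
    proteomes: Dict[str, List[Tuple[str, str]]],
    score_min: float = 50.0,
    evalue_max: float = 1e-10,
) -> SimilarityGraph:
    """All-vs-all local alignment; edges kept when both thresholds pass.

    A shared-4-mer prefilter skips hopeless pairs (a local alignment
    scoring >= 50 bits of BLOSUM62 raw score requires substantial exact
    overlap, which implies common 4-mers).
    """
    if len(proteomes) < 2:
        raise ValueError("need at least 2 genomes")
    nodes: List[str] = []
    seqs: List[str] = []
    for genome, prots in proteomes.items():
        if not prots:
            raise ValueError(f"empty proteome for {genome}")
        for pid, seq in prots:
            nodes.append(pid)
            seqs.append(seq)
    kmer_sets = [frozenset(s[i:i + 4] for i in range(len(s) - 3)) for s in seqs]
    aligner = _aligner()
    edges: List[Tuple[int, int, float]] = []
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            if not (kmer_sets[i] & kmer_sets[j]):
                continue
            score = float(aligner.score(seqs[i], seqs[j]))
            if score >= score_min and evalue_proxy(score, len(seqs[i]), len(seqs[j])) <= evalue_max:
                edges.append((i, j, score))
    return SimilarityGraph(nodes=nodes, edges=edges,
                           score_min=score_min, evalue_max=evalue_max)


def mcl_cluster(
    graph: SimilarityGraph,
    inflation: float = 1.5,
    prune: float = 1e-5,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> List[List[str]]:
    """Markov clustering of the similarity graph into gene families.

    The score matrix (plus unit self-loops) is column-normalized, then
    expansion (matrix squaring) and inflation (elementwise power with
    renormalization and pruning) are iterated to convergence; families
    are the connected components of the attractor matrix.  Singleton
    proteins form their own families.
    """
    n = graph.n
    if n == 0:
        raise ValueError("empty graph")
    M = np.zeros((n, n))
    for i, j, s in graph.edges:
        M[i, j] = M[j, i] = max(M[i, j], s)
    np.fill_diagonal(M, np.maximum(M.max(axis=0), 1.0))  # self-loops
    M /= M.sum(axis=0, keepdims=True)
    converged = False
    for _ in range(max_iter):
        prev = M
        M = M @ M                      # expansion
        M = np.power(M, inflation)     # inflation
        M[M < prune] = 0.0
        colsum = M.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        M /= colsum
        if np.abs(M - prev).max() < tol:
            converged = True
            break
    if not converged:
        import warnings
        warnings.warn("MCL did not converge; interpreting current state", RuntimeWarning)
    _, labels = connected_components(csr_matrix(M > 0), directed=False)
    families: Dict[int, List[str]] = {}
    for idx, lab in enumerate(labels):
        families.setdefault(lab, []).append(graph.nodes[idx])
    return [sorted(f) for f in sorted(families.values(), key=lambda f: f[0])]


def genome_of_protein(protein_id: str) -> str:
    if "|" not in protein_id:
        raise ValueError(f"protein id {protein_id!r} is not genome-qualified")
    return protein_id.split("|", 1)[0]


def categorize_families(
    families: Sequence[Sequence[str]],
    genomes: Sequence[str],
) -> PanGenomeResult:
    """Assign core/dispensable/unique by genome span.

    Paralogs are allowed: 'present in a genome' means at least one member.
    """
    genome_set = set(genomes)
    genome_of: Dict[str, str] = {}
    category: List[str] = []
    for fam in families:
        spanned = set()
        for pid in fam:
            g = genome_of_protein(pid)
            if g not in genome_set:
                raise ValueError(f"protein {pid} maps to unknown genome {g}")
            genome_of[pid] = g
            spanned.add(g)
        if spanned == genome_set:
            category.append("core")
        elif len(spanned) == 1:
            category.append("unique")
        else:
            category.append("dispensable")
    return PanGenomeResult(families=[list(f) for f in families], category=category,
                           genome_of=genome_of, genomes=list(genomes))


def pan_distance_matrix(result: PanGenomeResult) -> np.ndarray:
    """1 - Jaccard similarity of family presence/absence between genomes."""
    presence = {g: set() for g in result.genomes}
    for k, fam in enumerate(result.families):
        for pid in fam:
            presence[result.genome_of[pid]].add(k)
    n = len(result.genomes)
    D = np.zeros((n, n))
    for a in range(n):
        fa = presence[result.genomes[a]]
        if not fa:
            raise ValueError(f"genome {result.genomes[a]} has no families")
        for b in range(a + 1, n):
            fb = presence[result.genomes[b]]
            union = len(fa | fb)
            D[a, b] = D[b, a] = 1.0 - len(fa & fb) / union
    result.distance_matrix = D
    return D


class _NJNode:
    __slots__ = ("name", "children")

    def __init__(self, name: Optional[str] = None,
                 children: Optional[List[Tuple["_NJNode", float]]] = None):
        self.name = name
        self.children = children or []

    def newick(self) -> str:
        if not self.children:
            return self.name
        inner = ",".join(f"{child.newick()}:{bl:.10f}" for child, bl in self.children)
        return f"({inner})"


def neighbor_joining(distances: np.ndarray, names: Sequence[str]) -> Tuple[str, int]:
    """Classic neighbour joining; returns (newick string, #negative branch
    lengths clamped to zero).

    The Q-criterion picks the pair to join; branch lengths follow the
    standard formulas; the final three nodes are joined into an unrooted
    trifurcation.
    """
    D = np.asarray(distances, dtype=float).copy()
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be square and symmetric")
    if n < 3:
        raise ValueError("need at least 3 taxa")
    nodes: List[_NJNode] = [_NJNode(name) for name in names]
    clamped = 0

    while len(nodes) > 3:
        m = len(nodes)
        row_sums = D.sum(axis=1)
        Q = (m - 2) * D - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = np.unravel_index(np.argmin(Q), Q.shape)
        if i > j:
            i, j = j, i
        dij = D[i, j]
        bi = 0.5 * dij + (row_sums[i] - row_sums[j]) / (2 * (m - 2))
        bj = dij - bi
        if bi < 0:
            bi, clamped = 0.0, clamped + 1
        if bj < 0:
            bj, clamped = 0.0, clamped + 1
        new = _NJNode(children=[(nodes[i], bi), (nodes[j], bj)])
        d_new = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.empty((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = d_new[keep]
        D2[-1, -1] = 0.0
        D = D2
        nodes = [nodes[k] for k in keep] + [new]

    # join the final three into an unrooted star
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    b0 = 0.5 * (d01 + d02 - d12)
    b1 = 0.5 * (d01 + d12 - d02)
    b2 = 0.5 * (d02 + d12 - d01)
    lengths = []
    for b in (b0, b1, b2):
        if b < 0:
            b, clamped = 0.0, clamped + 1
        lengths.append(b)
    root = _NJNode(children=list(zip(nodes, lengths)))
    return root.newick() + ";", clamped


def pan_genome_pipeline(
    proteomes: Dict[str, List[Tuple[str, str]]],
    score_min: float = 50.0,
    evalue_max: float = 1e-10,
    inflation: float = 1.5,
) -> PanGenomeResult:
    """score -> MCL -> categorize -> distances -> NJ tree."""
    graph = score_pairs(proteomes, score_min=score_min, evalue_max=evalue_max)
    families = mcl_cluster(graph, inflation=inflation)
    result = categorize_families(families, sorted(proteomes))
    D = pan_distance_matrix(result)
    if len(result.genomes) >= 3:
        result.tree_newick, result.negative_branches_clamped = neighbor_joining(
            D, result.genomes)
    return result


def family_table(result: PanGenomeResult) -> pd.DataFrame:
    rows = []
    for k, (fam, cat) in enumerate(zip(result.families, result.category)):
        for pid in fam:
            rows.append({"family": k, "category": cat,
                         "genome": result.genome_of[pid], "protein": pid})
    return pd.DataFrame(rows, columns=["family", "category", "genome", "protein"])
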