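"""Synthetic bacterial genomes, dRNA-Seq 5'-end profiles and proteomes.

Every downstream stage of the pipeline (TSS calling, positional
classification, promoter/RBS motif analysis, pan-genome clustering) is
exercised against data produced here, with complete ground truth: which
positions are genuine transcription start sites and of which positional
class, where the -10/-35 hexamers and ribosome binding sites were
planted, and which protein belongs to which gene family.

The read model is deliberately minimal: 5'-end counts at a true TSS are
Poisson with mean ``tss_read_mean`` in the exonuclease-treated (TEX+)
library and mean ``tss_read_mean / tex_enrichment`` in the untreated
(TEX-) library; processed 5' ends have the inverted ratio; everywhere
else a low uniform Poisson background applies.  Setting
``poisson_counts=False`` replaces draws by their rounded means, giving a
noise-free profile for exact-recovery tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .genome import Gene, GenomeRecord, reverse_complement, tss_offset_position, write_fasta, write_gff3
from .profiles import EndCountProfile, profile_filename, write_bedgraph

BASES = np.frombuffer(b"ACGT", dtype="S1")
PURINES = ("A", "G")
PYRIMIDINES = ("C", "T")
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic genome/transcriptome generator.

    Defaults mirror the promoter and 5'UTR architecture typical of a
    firmicute primary transcriptome: TATAAT/TTGACA hexamers with a
    16-18 nt spacer, pyrimidine at -1 / purine at +1, GGAGR ribosome
    binding sites 5-10 nt upstream of the start codon, and a 5'UTR
    length distribution with its mode in the 20-29 nt bin and a long
    tail beyond 100 nt.
    """

    genome_length: int = 200_000
    n_genes: int = 100
    gene_length: Tuple[int, int] = (300, 900)
    gc_fraction: float = 0.47
    p_primary_tss: float = 0.9
    p_secondary: float = 0.1
    secondary_strength: float = 0.4
    # 5'UTR length: mixture of a shifted gamma body, a uniform 20-29 nt
    # spike (the modal bin) and a uniform long tail beyond 100 nt.  The
    # defaults give median ~36 nt, ~88% below 100 nt and ~28% in 20-29.
    utr_short_shift: int = 4
    utr_short_shape: float = 4.4
    utr_short_scale: float = 7.6
    utr_spike_prob: float = 0.10
    p_long_utr: float = 0.12
    utr_long_range: Tuple[int, int] = (101, 280)
    minus10_consensus: str = "TATAAT"
    minus35_consensus: str = "TTGACA"
    p_minus35_present: float = 0.5
    spacer_dist: Tuple[int, ...] = (16, 17, 18)
    per_base_mutation_rate: float = 0.05
    p_pyrimidine_minus1: float = 0.863
    p_purine_plus1: float = 0.938
    rbs_consensus: str = "GGAGR"
    rbs_spacer_dist: Tuple[int, ...] = (5, 6, 7, 8, 9, 10)
    tss_read_mean: float = 100.0
    tex_enrichment: float = 10.0
    background_rate: float = 0.02
    n_processed_sites: int = 50
    n_antisense_tss: int = 10
    n_intergenic_tss: int = 10
    poisson_counts: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        for name in ("p_primary_tss", "p_secondary", "p_minus35_present",
                     "per_base_mutation_rate", "p_long_utr",
                     "p_pyrimidine_minus1", "p_purine_plus1"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.tex_enrichment <= 1:
            raise ValueError("tex_enrichment must exceed 1")
        if not set(self.spacer_dist) <= {16, 17, 18}:
            raise ValueError("spacer_dist support must be within {16,17,18}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class TrueTSS:
    position: int
    strand: str
    tss_class: str  # P, S, I, A or N
    gene: Optional[str]
    weight: float = 1.0
    utr_length: Optional[int] = None


@dataclass
class PromoterTruth:
    tss_position: int
    strand: str
    minus10: Tuple[int, int]  # genomic span, 1-based inclusive
    minus35: Optional[Tuple[int, int]]
    spacer: Optional[int]


@dataclass
class RBSTruth:
    gene: str
    span: Tuple[int, int]
    spacer: int
    sequence: str


@dataclass
class GroundTruth:
    """Everything the generator planted, for downstream validation."""

    true_tss: List[TrueTSS] = field(default_factory=list)
    promoters: List[PromoterTruth] = field(default_factory=list)
    rbs_sites: List[RBSTruth] = field(default_factory=list)
    processed_sites: List[Tuple[int, str]] = field(default_factory=list)
    family_assignment: Dict[str, int] = field(default_factory=dict)
    family_category: Dict[int, str] = field(default_factory=dict)

    def tss_of_class(self, cls: str) -> List[TrueTSS]:
        return [t for t in self.true_tss if t.tss_class == cls]


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(BASES, size=n, p=p)


def _mutate(rng: np.random.Generator, motif: str, rate: float) -> str:
    out = []
    for b in motif:
        if rate > 0 and rng.random() < rate:
            out.append(rng.choice([c for c in "ACGT" if c != b]))
        else:
            out.append(b)
    return "".join(out)


def _resolve_degenerate(rng: np.random.Generator, motif: str) -> str:
    """Resolve IUPAC R/Y codes to concrete bases."""
    table = {"R": PURINES, "Y": PYRIMIDINES}
    return "".join(rng.choice(table[b]) if b in table else b for b in motif)


class _SeqEditor:
    """Writes motif strings into a mutable circular base array, strand-aware."""

    def __init__(self, arr: np.ndarray):
        self.arr = arr
        self.n = len(arr)

    def plant(self, tss: int, strand: str, off_start: int, off_end: int, motif: str) -> Tuple[int, int]:
        """Plant ``motif`` (5'->3' in transcript orientation) at TSS-relative
        offsets ``off_start..off_end``; returns the genomic span (lo, hi)."""
        positions = [tss_offset_position(tss, strand, o, self.n)
                     for o in _offset_range(off_start, off_end)]
        written = motif if strand == "+" else reverse_complement(motif)
        lo, hi = min(positions), max(positions)
        for i, p in enumerate(range(lo, hi + 1)):
            self.arr[(p - 1) % self.n] = written[i].encode()
        return lo, hi

    def set_base(self, position: int, base: str) -> None:
        self.arr[(position - 1) % self.n] = base.encode()


def _offset_range(a: int, b: int) -> List[int]:
    """Inclusive offset range skipping 0 (offsets -1 and +1 are adjacent)."""
    return [o for o in range(a, b + 1) if o != 0]


def _sample_utr(rng: np.random.Generator, cfg: SimulationConfig) -> int:
    if rng.random() < cfg.p_long_utr:
        lo, hi = cfg.utr_long_range
        return int(rng.integers(lo, hi + 1))
    if rng.random() < cfg.utr_spike_prob:
        return int(rng.integers(20, 30))
    g = rng.gamma(cfg.utr_short_shape, cfg.utr_short_scale)
    return cfg.utr_short_shift + int(round(g))


def generate_genome(config: SimulationConfig) -> Tuple[GenomeRecord, GroundTruth]:
    """Build a circular genome with planted genes, promoters and TSSs.

    Genes are laid out one per equal-size slot with a fixed upstream
    margin so that promoter elements never collide with a neighbouring
    ORF.  Raises if the genome is too short for the requested gene count.
    """
    cfg = config
    rng = cfg.rng()
    slot = cfg.genome_length // max(cfg.n_genes, 1)
    margin = 400  # room upstream of the start codon for UTR + promoter
    max_gene = cfg.gene_length[1]
    if cfg.n_genes > 0 and slot < max_gene + margin + 50:
        raise ValueError(
            f"genome of {cfg.genome_length} bp cannot hold {cfg.n_genes} genes of up to "
            f"{max_gene} bp with a {margin} bp regulatory margin"
        )

    arr = _random_bases(rng, cfg.genome_length, cfg.gc_fraction).copy()
    editor = _SeqEditor(arr)
    truth = GroundTruth()
    genes: List[Gene] = []

    for i in range(cfg.n_genes):
        slot_start = i * slot + 1
        glen = int(rng.integers(cfg.gene_length[0], cfg.gene_length[1] + 1))
        strand = str(rng.choice(["+", "-"]))
        if strand == "+":
            start = slot_start + margin
            end = start + glen - 1
        else:
            end = slot_start + slot - 1 - margin
            start = end - glen + 1
        gene = Gene(id=f"gene{i:04d}", start=start, end=end, strand=strand)
        genes.append(gene)
        # start / stop codons in transcript orientation
        sc = gene.start_codon
        editor.plant(sc, strand, +1, +3, "ATG")
        stop_first = gene.end - 2 if strand == "+" else gene.start + 2
        editor.plant(stop_first, strand, +1, +3, "TAA")

        if rng.random() >= cfg.p_primary_tss:
            continue
        utr = _sample_utr(rng, cfg)
        tss = tss_offset_position(sc, strand, -utr, cfg.genome_length) if utr > 0 else sc
        _plant_promoter(editor, rng, cfg, truth, tss, strand)
        truth.true_tss.append(TrueTSS(tss, strand, "P", gene.id, 1.0, utr))
        _plant_rbs(editor, rng, cfg, truth, gene, utr)

        if rng.random() < cfg.p_secondary:
            gap = int(rng.integers(10, 41))
            utr2 = utr + gap if utr + gap <= 295 else utr - gap
            if utr2 > 0:
                tss2 = tss_offset_position(sc, strand, -utr2, cfg.genome_length)
                _plant_promoter(editor, rng, cfg, truth, tss2, strand)
                truth.true_tss.append(
                    TrueTSS(tss2, strand, "S", gene.id, cfg.secondary_strength, utr2))

    _plant_orphan_tss(editor, genes, rng, cfg, truth)
    genome = GenomeRecord(id="synthetic_genome", seq=arr.tobytes().decode(), features=genes)
    _plant_processed_sites(genome, rng, cfg, truth)
    return genome, truth


def _plant_promoter(editor: _SeqEditor, rng: np.random.Generator, cfg: SimulationConfig,
                    truth: GroundTruth, tss: int, strand: str) -> None:
    """-10 hexamer with its 3' end 7 nt upstream of the TSS (offsets -12..-7);
    optional -35 separated by the sampled spacer; -1/+1 composition biases."""
    m10 = _mutate(rng, cfg.minus10_consensus, cfg.per_base_mutation_rate)
    span10 = editor.plant(tss, strand, -12, -7, m10)
    minus35_span = None
    spacer = None
    if rng.random() < cfg.p_minus35_present:
        spacer = int(rng.choice(cfg.spacer_dist))
        m35 = _mutate(rng, cfg.minus35_consensus, cfg.per_base_mutation_rate)
        # -35 end offset sits `spacer` nt upstream of the -10 start offset (-12)
        end_off = -13 - spacer
        minus35_span = editor.plant(tss, strand, end_off - 5, end_off, m35)
    minus1 = str(rng.choice(PYRIMIDINES if rng.random() < cfg.p_pyrimidine_minus1 else PURINES))
    plus1 = str(rng.choice(PURINES if rng.random() < cfg.p_purine_plus1 else PYRIMIDINES))
    editor.plant(tss, strand, -1, -1, minus1)
    editor.plant(tss, strand, +1, +1, plus1)
    truth.promoters.append(PromoterTruth(tss, strand, span10, minus35_span, spacer))


def _plant_rbs(editor: _SeqEditor, rng: np.random.Generator, cfg: SimulationConfig,
               truth: GroundTruth, gene: Gene, utr: int) -> None:
    spacer = int(rng.choice(cfg.rbs_spacer_dist))
    width = len(cfg.rbs_consensus)
    if utr < spacer + width:
        return  # UTR too short to hold the RBS at the sampled spacing
    seq = _mutate(rng, _resolve_degenerate(rng, cfg.rbs_consensus), cfg.per_base_mutation_rate)
    sc = gene.start_codon
    end_off = -spacer - 1
    span = editor.plant(sc, gene.strand, end_off - width + 1, end_off, seq)
    truth.rbs_sites.append(RBSTruth(gene.id, span, spacer, seq))


def _positional_class(position: int, strand: str, genes: Sequence[Gene],
                      genome_length: int, upstream: int = 300, downstream: int = 100) -> str:
    """Positional class a count-free classifier would assign (P folded into S)."""
    half = genome_length // 2
    for g in genes:
        d = position - g.start_codon if g.strand == "+" else g.start_codon - position
        d = (d + half) % genome_length - half
        if g.strand == strand and -upstream <= d <= downstream:
            return "P"
    for g in genes:
        if g.contains(position):
            return "I" if g.strand == strand else "A"
    return "N"


def _plant_orphan_tss(editor: _SeqEditor, genes: Sequence[Gene], rng: np.random.Generator,
                      cfg: SimulationConfig, truth: GroundTruth) -> None:
    """Plant antisense and intergenic TSSs (with their own promoters - an
    ncRNA TSS is a genuine initiation site) at positions whose positional
    class is unambiguous, avoiding collisions with planted sense TSSs."""
    taken = {(t.position, t.strand) for t in truth.true_tss}

    def admit(cls_wanted: str, n_wanted: int) -> None:
        placed = 0
        for _ in range(200 * max(n_wanted, 1)):
            if placed >= n_wanted:
                break
            pos = int(rng.integers(1, cfg.genome_length + 1))
            strand = str(rng.choice(["+", "-"]))
            if (pos, strand) in taken:
                continue
            if any(abs(pos - p) <= 60 and s == strand for p, s in taken):
                continue
            if _positional_class(pos, strand, genes, cfg.genome_length) != cls_wanted:
                continue
            _plant_promoter(editor, rng, cfg, truth, pos, strand)
            truth.true_tss.append(TrueTSS(pos, strand, cls_wanted, None, 1.0, None))
            taken.add((pos, strand))
            placed += 1
        if placed < n_wanted:
            raise RuntimeError(f"could not place {n_wanted} class-{cls_wanted} TSSs")

    admit("A", cfg.n_antisense_tss)
    admit("N", cfg.n_intergenic_tss)


def _plant_processed_sites(genome: GenomeRecord, rng: np.random.Generator,
                           cfg: SimulationConfig, truth: GroundTruth) -> None:
    taken = {(t.position, t.strand) for t in truth.true_tss}
    placed = 0
    for _ in range(200 * max(cfg.n_processed_sites, 1)):
        if placed >= cfg.n_processed_sites:
            break
        pos = int(rng.integers(1, cfg.genome_length + 1))
        strand = str(rng.choice(["+", "-"]))
        if any(abs(pos - p) <= 10 and s == strand for p, s in taken):
            continue
        truth.processed_sites.append((pos, strand))
        taken.add((pos, strand))
        placed += 1


def generate_end_profiles(
    genome: GenomeRecord, truth: GroundTruth, config: SimulationConfig,
) -> Tuple[Dict[str, EndCountProfile], Dict[str, EndCountProfile]]:
    """TEX+ and TEX- 5'-end count profiles, keyed by strand.

    True TSSs are enriched in TEX+ by ``tex_enrichment``-fold; processed
    sites carry the inverted ratio; a low uniform Poisson background is
    added everywhere.
    """
    cfg = config
    n = len(genome)
    rng = np.random.default_rng(cfg.seed + 1)

    def draw(mean: float) -> int:
        if mean <= 0:
            return 0
        return int(rng.poisson(mean)) if cfg.poisson_counts else int(round(mean))

    plus = {s: np.zeros(n, dtype=np.int64) for s in "+-"}
    minus = {s: np.zeros(n, dtype=np.int64) for s in "+-"}
    for t in truth.true_tss:
        if t.position < 1 or t.position > n:
            raise ValueError(f"TSS position {t.position} outside genome")
        mean = cfg.tss_read_mean * t.weight
        plus[t.strand][t.position - 1] += draw(mean)
        minus[t.strand][t.position - 1] += draw(mean / cfg.tex_enrichment)
    for pos, strand in truth.processed_sites:
        minus[strand][pos - 1] += draw(cfg.tss_read_mean)
        plus[strand][pos - 1] += draw(cfg.tss_read_mean / cfg.tex_enrichment)
    if cfg.background_rate > 0 and cfg.poisson_counts:
        for s in "+-":
            plus[s] += rng.poisson(cfg.background_rate, n)
            minus[s] += rng.poisson(cfg.background_rate, n)

    tex_plus = {s: EndCountProfile("texplus", s, plus[s]) for s in "+-"}
    tex_minus = {s: EndCountProfile("texminus", s, minus[s]) for s in "+-"}
    return tex_plus, tex_minus


def generate_proteomes(
    config: SimulationConfig,
    n_genomes: int,
    n_families: int,
    category_fractions: Tuple[float, float, float] = (0.3, 0.5, 0.2),
    identity: float = 0.9,
    length_range: Tuple[int, int] = (80, 200),
) -> Tuple[Dict[str, List[Tuple[str, str]]], GroundTruth]:
    """Multi-genome protein sets with planted core/dispensable/unique families.

    Each family descends from a random ancestral protein, point-mutated
    per genome to the requested identity (no indels).  Returns
    ``{genome: [(protein_id, sequence), ...]}`` plus ground truth mapping
    proteins to families and families to categories.
    """
    if n_genomes < 3:
        raise ValueError("n_genomes must be at least 3")
    if not 0 < identity <= 1:
        raise ValueError("identity must be in (0, 1]")
    if abs(sum(category_fractions) - 1.0) > 1e-9:
        raise ValueError("category_fractions must sum to 1")
    rng = np.random.default_rng(config.seed + 2)
    genome_names = [f"genome{i}" for i in range(n_genomes)]
    n_core = int(round(category_fractions[0] * n_families))
    n_unique = int(round(category_fractions[2] * n_families))
    n_disp = n_families - n_core - n_unique

    truth = GroundTruth()
    proteomes: Dict[str, List[Tuple[str, str]]] = {g: [] for g in genome_names}
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1")

    fam_id = 0
    for category, count in (("core", n_core), ("dispensable", n_disp), ("unique", n_unique)):
        for _ in range(count):
            length = int(rng.integers(length_range[0], length_range[1] + 1))
            ancestor = rng.choice(aa, size=length)
            if category == "core":
                members = list(range(n_genomes))
            elif category == "unique":
                members = [int(rng.integers(n_genomes))]
            else:
                k = int(rng.integers(2, n_genomes))  # 2 .. n_genomes-1
                members = sorted(rng.choice(n_genomes, size=k, replace=False).tolist())
            truth.family_category[fam_id] = category
            for gi in members:
                seq = ancestor.copy()
                if identity < 1:
                    mask = rng.random(length) < (1 - identity)
                    for j in np.flatnonzero(mask):
                        choices = aa[aa != seq[j]]
                        seq[j] = rng.choice(choices)
                pid = f"{genome_names[gi]}|fam{fam_id:04d}"
                proteomes[genome_names[gi]].append((pid, seq.tobytes().decode()))
                truth.family_assignment[pid] = fam_id
            fam_id += 1
    return proteomes, truth


def write_fixtures(
    directory: str | Path,
    genome: GenomeRecord,
    truth: GroundTruth,
    tex_plus: Dict[str, EndCountProfile],
    tex_minus: Dict[str, EndCountProfile],
    config: SimulationConfig | None = None,
    proteomes: Dict[str, List[Tuple[str, str]]] | None = None,
) -> Dict[str, Path]:
    """Serialize a full synthetic dataset; returns the paths written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}

    paths["fasta"] = directory / "genome.fasta"
    write_fasta(genome, paths["fasta"])
    paths["gff3"] = directory / "annotation.gff3"
    write_gff3(genome, paths["gff3"])
    for lib, profs in (("texplus", tex_plus), ("texminus", tex_minus)):
        for strand, prof in profs.items():
            p = directory / profile_filename(lib, strand)
            write_bedgraph(prof, p)
            paths[f"{lib}_{strand}"] = p

    rows = [
        {"position": t.position, "strand": t.strand, "class": t.tss_class,
         "gene": t.gene or "", "weight": t.weight,
         "utr_length": t.utr_length if t.utr_length is not None else ""}
        for t in truth.true_tss
    ]
    paths["truth"] = directory / "ground_truth.tsv"
    pd.DataFrame(rows, columns=["position", "strand", "class", "gene", "weight", "utr_length"]).to_csv(
        paths["truth"], sep="\t", index=False)

    if config is not None:
        paths["config"] = directory / "config.yaml"
        with open(paths["config"], "w") as fh:
            yaml.safe_dump(dataclasses.asdict(config), fh)
    if proteomes:
        pdir = directory / "proteomes"
        pdir.mkdir(exist_ok=True)
        for gname, prots in proteomes.items():
            p = pdir / f"{gname}.faa"
            with open(p, "w") as fh:
                for pid, seq in prots:
                    fh.write(f">{pid}\n{seq}\n")
            paths[f"proteome_{gname}"] = p
    return paths
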