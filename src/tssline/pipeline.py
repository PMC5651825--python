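"""End-to-end orchestration: genome stats -> TSS calling -> classification
-> promoter/UTR/RBS analysis -> (optional) pan-genome.

A :class:`PipelineConfig` names the input files (genome FASTA, GFF3, the
four strand-specific bedGraphs of the TEX+/TEX- libraries and optionally
a proteome directory), carries stage parameters and a seed, and
validates that every referenced file exists before any stage runs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import yaml

from . import genome as genome_io
from . import genome_stats, motifs, pangenome, report as report_mod, utr as utr_mod
from .tss_classification import ClassificationWindows, classification_table, classify_tss, summarize_classes
from .tss_detection import DetectionParams, call_tss, load_end_counts, write_tss_bed, write_tss_tsv

logger = logging.getLogger("tssline")


@dataclass
class PipelineConfig:
    genome_fasta: Path
    annotation_gff3: Path
    texplus_fwd: Path
    texplus_rev: Path
    texminus_fwd: Path
    texminus_rev: Path
    proteome_dir: Optional[Path] = None
    output_dir: Path = Path("tssline_out")
    detection: DetectionParams = field(default_factory=DetectionParams)
    windows: ClassificationWindows = field(default_factory=ClassificationWindows)
    motif_width: int = 6
    motif_restarts: int = 20
    n_permutations: int = 0  # 0 disables the permutation test in the pipeline
    mcl_inflation: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("genome_fasta", "annotation_gff3", "texplus_fwd",
                     "texplus_rev", "texminus_fwd", "texminus_rev"):
            setattr(self, name, Path(getattr(self, name)))
        self.output_dir = Path(self.output_dir)
        if self.proteome_dir is not None:
            self.proteome_dir = Path(self.proteome_dir)

    def validate(self) -> None:
        for name in ("genome_fasta", "annotation_gff3", "texplus_fwd",
                     "texplus_rev", "texminus_fwd", "texminus_rev"):
            p = getattr(self, name)
            if not p.exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")
        if self.proteome_dir is not None and not self.proteome_dir.is_dir():
            raise FileNotFoundError(f"proteome_dir: {self.proteome_dir} is not a directory")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        det = DetectionParams(**raw.pop("detection", {}))
        win = ClassificationWindows(**raw.pop("windows", {}))
        return cls(detection=det, windows=win, **raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; writes per-stage TSV/BED/JSON artifacts under
    ``config.output_dir`` and returns the assembled report."""
    config.validate()
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)

    logger.info("[stats] loading genome and annotation")
    genome = genome_io.read_fasta(config.genome_fasta)
    genome_io.attach_annotation(genome, genome_io.read_gff3(config.annotation_gff3))
    gsum = genome_stats.genome_summary(genome)
    skew = genome_stats.cumulative_gc_skew(genome)
    skew.to_frame().to_csv(out / "gc_skew.tsv", sep="\t", index=False)

    logger.info("[tss] loading 5'-end profiles and calling TSSs")
    tex_plus = load_end_counts({"+": config.texplus_fwd, "-": config.texplus_rev},
                               len(genome), "texplus")
    tex_minus = load_end_counts({"+": config.texminus_fwd, "-": config.texminus_rev},
                                len(genome), "texminus")
    records = call_tss(tex_plus, tex_minus, config.detection)
    write_tss_tsv(records, out / "tss.tsv")
    write_tss_bed(records, out / "tss.bed")

    logger.info("[classify] assigning positional classes")
    classify_tss(records, genome.features, len(genome), config.windows)
    classification_table(records).to_csv(out / "tss_classified.tsv", sep="\t", index=False)
    csum = summarize_classes(records, genome.features)

    logger.info("[motifs] promoter, composition, UTR and RBS analysis")
    minus10_windows = [motifs.extract_window(t, genome, -20, -1) for t in records]
    minus35_windows = [motifs.extract_window(t, genome, -50, -21) for t in records]
    m10 = motifs.discover_motif(minus10_windows, width=config.motif_width,
                                n_restarts=config.motif_restarts, seed=config.seed)
    m35 = motifs.discover_motif(minus35_windows, width=config.motif_width,
                                n_restarts=config.motif_restarts, seed=config.seed + 1)
    if config.n_permutations:
        m10.p_value = motifs.motif_significance(m10, minus10_windows,
                                                config.n_permutations, seed=config.seed)
        m35.p_value = motifs.motif_significance(m35, minus35_windows,
                                                config.n_permutations, seed=config.seed + 1)
    (out / "minus10_motif.meme.txt").write_text(m10.to_meme_text("MINUS10"))
    (out / "minus35_motif.meme.txt").write_text(m35.to_meme_text("MINUS35"))
    spacer_info = motifs.assign_minus35_and_spacers(m10, m35, len(records))
    comp = motifs.composition_at_tss(records, genome)

    primaries = [t for t in records if t.tss_class == "P"]
    ustats = utr_mod.compute_utrs(primaries, genome.features)
    utr_lengths = {t.gene: t.utr_length for t in primaries}
    rbs_genes = [g for g in genome.features if g.id in utr_lengths]
    rbs_hits = utr_mod.find_rbs(rbs_genes, genome, utr_lengths)
    rbs_hist = utr_mod.rbs_spacer_histogram(rbs_hits)

    motif_summary = {
        "minus10_consensus": m10.consensus,
        "minus35_consensus": m35.consensus,
        "minus10_fraction_conserved": spacer_info["fraction_minus10"],
        "minus35_fraction_conserved": spacer_info["fraction_both"],
        "minus10_p_value": m10.p_value,
        "minus35_p_value": m35.p_value,
        "spacer_histogram": {str(k): v for k, v in spacer_info["spacer_histogram"].items()},
        "architecture": spacer_info["architecture"],
        "pyrimidine_minus1_fraction": comp["pyrimidine_minus1"],
        "purine_plus1_fraction": comp["purine_plus1"],
    }
    utr_summary = {
        "n_utrs": ustats.n,
        "median_nt": ustats.median,
        "fraction_lt_100": ustats.fraction_lt_100,
        "n_long_utrs": len(ustats.long_utrs),
        "histogram": ustats.histogram,
    }
    rbs_summary = {
        "n_hits": len(rbs_hits),
        "spacer_histogram": {str(k): v for k, v in rbs_hist.items()},
        "fraction_spacer_5_10": (
            sum(v for k, v in rbs_hist.items() if 5 <= k <= 10) / len(rbs_hits)
            if rbs_hits else 0.0),
    }

    pan_summary = None
    if config.proteome_dir is not None:
        logger.info("[pangenome] clustering proteomes")
        proteomes = pangenome.read_proteomes(config.proteome_dir)
        result = pangenome.pan_genome_pipeline(proteomes, inflation=config.mcl_inflation)
        pangenome.family_table(result).to_csv(out / "families.tsv", sep="\t", index=False)
        if result.tree_newick:
            (out / "pangenome_tree.nwk").write_text(result.tree_newick + "\n")
        pan_summary = {
            "n_genomes": len(result.genomes),
            "family_counts": result.family_counts(),
            "gene_counts": result.gene_counts(),
            "per_genome_gene_counts": result.per_genome_gene_counts(),
        }

    rep = report_mod.build_report(gsum, csum, motif_summary, utr_summary,
                                  rbs_summary, pan_summary)
    report_mod.write_report(rep, out / "report.json")
    return rep
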