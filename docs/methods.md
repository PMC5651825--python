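# Methods

This note documents the algorithms and conventions implemented in
`tssline`, in the order the pipeline runs them. Coordinates are 1-based
and inclusive throughout the API (GFF3 convention); bedGraph files use
the format's native 0-based half-open intervals. All genomes are
treated as circular.

## Synthetic data generation

`simulate.generate_genome` lays `n_genes` ORFs on alternating strands in
equal slots along a random-composition chromosome (default GC 0.47),
keeping a 400 nt regulatory margin per gene. For each gene it plants,
with configurable probabilities: a primary TSS at a distance drawn from
the 5′UTR model; a −10 hexamer (TATAAT) at TSS offsets −12..−7; with
probability `p_minus35_present` a −35 hexamer (TTGACA) whose last base
sits `spacer` nt upstream of the −10, `spacer` drawn from {16, 17, 18};
a pyrimidine at −1 and purine at +1 with the configured probabilities; a
GGAGR ribosome-binding site 5–10 nt upstream of the start codon; and
optionally a weaker secondary TSS. Planted motif instances are mutated
base-wise at `per_base_mutation_rate`. Antisense and intergenic TSSs
receive full promoters and are placed only where their positional class
is unambiguous. Processing sites (TEX− signal without TEX+ enrichment)
are planted away from true TSSs.

The 5′UTR length model is a three-part mixture: a gamma body
(shape 4.4, scale 7.6, shifted by 4 nt), a uniform spike on 20–29 nt
(weight 0.10) and a uniform long tail on 101–280 nt (weight 0.12).
These parameters were chosen so the planted distribution has the
summary statistics reported for a real acetogen primary transcriptome
(median ≈ 36 nt, ≈ 88% below 100 nt, ≈ 28% in the 20–29 nt bin); they
are generator *conditions*, not quantities fitted to this package's own
output.

`generate_end_profiles` converts the planted TSS weights into per-strand
5′-end count vectors: TEX+ counts are (optionally Poisson-distributed)
draws around `tss_read_mean`, TEX− counts are reduced by the configured
`tex_enrichment` factor, and uniform background noise is added at
`background_rate`. `generate_proteomes` builds gene families with a
planted core/dispensable/unique composition by mutating a family
ancestor to a configurable within-family identity.

## Genome statistics

GC content excludes ambiguous bases from numerator and denominator.
Coding density is the fraction of genome positions covered by at least
one CDS (union over both strands). GC skew is `(G−C)/(G+C)` in tiling
1 kb windows (the final window wraps); the replication origin is
reported at the window midpoint of the global *minimum* of the
cumulative skew and the terminus at the global maximum, which follows
from leading-strand G enrichment. A constant skew profile raises an
error rather than reporting arbitrary extrema.

## TSS detection

Both libraries are normalized to counts per million, with library size
summed over both strand vectors. Position `i` on a strand is a TSS
candidate when its raw TEX+ count is ≥ `min_count` (default 10) and

```
(cpm_plus[i] + 1) / (cpm_minus[i] + 1) >= min_enrichment   # default 2.0
```

The +1 pseudocount keeps the ratio defined at zero TEX− coverage while
damping low-count noise. Candidates separated by ≤ 5 nt on one strand
are merged transitively (including across the circular origin); the
cluster's representative is the position with the highest TEX+ count,
ties resolved to the transcriptionally upstream position. Every
reported TSS therefore satisfies both thresholds itself.

## Positional classification

For each TSS, every same-strand gene whose start codon lies within
[−300, +100] of it (strand-aware, circularly wrapped) is a candidate;
the nearest start codon wins, ties going to the gene whose start codon
is downstream of the TSS (i.e. the TSS is upstream of it). Within a
gene, the candidate with the highest TEX+ count is primary (ties to the
most upstream), the others secondary. Unassigned TSSs are internal if
inside a same-strand ORF, antisense if opposite an ORF, intergenic
otherwise. The 5′UTR length of a P/S TSS is the distance from the TSS
to the base before the start codon; 0 means leaderless, negative values
(initiation downstream of the annotated start) are flagged separately
rather than binned. The 100 nt downstream bound is a parameter; a
150 nt variant is also in circulation and can be selected via
`ClassificationWindows(downstream=150)`.

## Promoter motif discovery

Windows of −20..−1 (for the −10 element) and −50..−21 (for the −35) are
extracted for every TSS; offsets skip 0, +1 being the TSS base itself,
and minus-strand windows are reverse-complemented. A ZOOPS
(zero-or-one occurrence per sequence) EM mixture is fitted: each window
either contains one motif occurrence at an unknown offset or is pure
background. The E-step computes posterior offset weights per window;
the M-step re-estimates the position frequency matrix (pseudocount
0.25 per cell) and the occurrence prior (initialized at 0.8). The best
of 20 random restarts is kept, then *phase-polished*: EM is re-seeded
from ±1 and ±2 column-shifted variants of the best matrix, which
removes the registration ambiguity that otherwise locks EM one column
off the true frame. A site is assigned to a window only when a single
offset carries the majority (> 0.5) of its posterior mass, so windows
whose posterior is split between competing offsets contribute to the
model but not to site-level statistics.

Motif significance is a permutation test on total information content
(relative entropy vs background, summed over columns): bases are
shuffled *within* each window, discovery is re-run with identical
reduced settings on observed and permuted data alike (which makes the
statistic exchangeable), and `p = (1 + #{perm ≥ obs}) / (1 + N)`.

For TSSs with both elements, the spacer is
`(−10 start offset) − (−35 end offset) − 1`; overlapping assignments
give negative spacers and are flagged. Initiation-site composition is
tabulated at offsets −2..+2, reporting the −1 pyrimidine and +1 purine
fractions.

## 5′UTRs and ribosome-binding sites

UTR lengths of primary TSSs are summarized as a 10 nt-bin histogram,
median, fraction < 100 nt and an explicit list of long (> 100 nt) UTRs.
The RBS search scans the −17..+3 window around each start codon with a
degenerate-consensus PWM for GGAGR (match probability 0.91 shared among
the allowed bases; R = A/G), accepting the best hit scoring within
2 bits of a perfect match. The spacer is the number of bases between
the last RBS base and the base before the start codon. When the known
5′UTR is shorter than the window, the window is truncated to the UTR
and the hit flagged.

## Pan-genome analysis

All protein pairs across genomes are aligned locally (Smith–Waterman
via Biopython's `PairwiseAligner`) with BLOSUM62, gap open −11 / extend
−1, after a shared-4-mer prefilter. An edge is kept when the raw score
is ≥ 50 and a Karlin–Altschul E-value proxy
(`K·m·n·exp(−λ·score)` with λ = 0.267, K = 0.041, the gapped-BLOSUM62
defaults, search space = product of sequence lengths) is ≤ 10⁻¹⁰. The
similarity graph is clustered with a dense-matrix Markov clustering
implementation: column-stochastic matrix with self-loops, alternating
expansion (matrix squaring) and inflation (elementwise power 1.5,
pruning below 10⁻⁵, renormalization) to convergence; families are the
connected components of the attractor matrix. Families spanning all
genomes are core, one genome unique, otherwise dispensable; a genome
"contains" a family if at least one member maps to it (paralogs count
individually in gene totals).

Genome-genome distances are 1 − Jaccard similarity of family
presence/absence sets. The tree is built by classic neighbour joining
(Q-matrix pair selection, standard branch-length formulas, final
unrooted trifurcation); negative branch lengths are clamped to zero and
counted. Both MCL and NJ are implemented in-package because their
exact update rules are part of the method; the test suite cross-checks
NJ against an independent phylogenetic library on additive matrices.

## Report

The JSON report collects genome statistics, class counts, motif
consensus strings and conservation fractions, spacer and composition
statistics, UTR/RBS summaries and pan-genome category counts. A
validator enforces that fractions lie in [0, 1] and counts are
non-negative. `report.percent` reproduces the one-decimal rounding used
in published summary tables so printed count ratios can be re-derived
exactly from their printed numerators and denominators.
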