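"""EM motif discovery, window extraction, spacer arithmetic and composition."""

import numpy as np
import pytest

from tssline import composition_at_tss, discover_motif, extract_window, motif_significance
from tssline.genome import GenomeRecord
from tssline.motifs import MotifModel, assign_minus35_and_spacers, encode
from tssline.simulate import SimulationConfig, generate_end_profiles, generate_genome
from tssline.tss_detection import TSSRecord


def _tss(position, strand="+"):
    return TSSRecord(position=position, strand=strand,
                     tex_plus_count=100, tex_minus_count=1, enrichment=10.0)


def _genome(seq):
    return GenomeRecord(id="g", seq=seq)


class TestExtractWindow:
    #            123456789012
    SEQ = "AAACCCTTTGGG"

    def test_plus_strand_window_skips_zero(self):
        genome = _genome(self.SEQ)
        # TSS at 7 (+): offsets -3..-1 are positions 4,5,6 = CCC; +1..+3 = TTT
        assert extract_window(_tss(7), genome, -3, -1) == "CCC"
        assert extract_window(_tss(7), genome, 1, 3) == "TTT"
        # -1..+1 spans exactly two bases (offset 0 does not exist)
        assert extract_window(_tss(7), genome, -1, 1) == "CT"

    def test_minus_strand_window_is_reverse_complemented(self):
        genome = _genome(self.SEQ)
        # TSS at 7 (-): transcript reads leftwards; -1 is position 8 (T->A),
        # +1 is position 7 (T->A); upstream -3..-1 = positions 10,9,8 = GTT -> CAA
        assert extract_window(_tss(7, "-"), genome, -3, -1) == "CAA"
        assert extract_window(_tss(7, "-"), genome, 1, 3) == "AGG"

    def test_circular_wrap(self):
        genome = _genome(self.SEQ)
        assert extract_window(_tss(1), genome, -2, -1) == "GG"

    def test_bad_range_raises(self):
        genome = _genome(self.SEQ)
        with pytest.raises(ValueError):
            extract_window(_tss(7), genome, 3, 1)


class TestDiscoverMotif:
    def _planted_windows(self, n=60, width=20, consensus="TATAAT",
                         mutation=0.0, seed=0):
        rng = np.random.default_rng(seed)
        windows = []
        for _ in range(n):
            w = list(rng.choice(list("ACGT"), size=width))
            off = int(rng.integers(0, width - len(consensus) + 1))
            for k, b in enumerate(consensus):
                if rng.random() < mutation:
                    b = str(rng.choice(list("ACGT")))
                w[off + k] = b
            windows.append("".join(w))
        return windows

    def test_recovers_clean_planted_consensus(self):
        windows = self._planted_windows()
        motif = discover_motif(windows, width=6, seed=1)
        assert motif.consensus == "TATAAT"
        assert motif.occupancy > 0.9

    def test_recovery_robust_to_point_mutations(self):
        hits = 0
        for seed in range(10):
            windows = self._planted_windows(mutation=0.1, seed=seed)
            motif = discover_motif(windows, width=6, seed=seed)
            hamming = sum(a != b for a, b in zip(motif.consensus, "TATAAT"))
            hits += hamming <= 1
        assert hits >= 9

    def test_planted_motif_has_more_information_than_uniform_noise(self):
        planted = discover_motif(self._planted_windows(), width=6, seed=2)
        rng = np.random.default_rng(3)
        noise = ["".join(rng.choice(list("ACGT"), size=20)) for _ in range(60)]
        random_motif = discover_motif(noise, width=6, seed=2)
        assert planted.total_information > random_motif.total_information

    def test_identical_sequences_give_near_degenerate_pfm(self):
        windows = ["TATAATGG"] * 30
        motif = discover_motif(windows, width=6, seed=0)
        # each column's counts sum to the posterior mass + 4 * pseudocount
        col_sums = motif.pfm.sum(axis=1)
        np.testing.assert_allclose(col_sums, col_sums[0])
        assert np.all(motif.probabilities.max(axis=1) > 0.9)

    def test_unequal_window_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            discover_motif(["ACGTACGT", "ACGTACG"], width=4)

    def test_width_exceeding_window_rejected(self):
        with pytest.raises(ValueError):
            discover_motif(["ACGTA"] * 5, width=6)


class TestSignificance:
    def test_planted_motif_is_significant(self):
        windows = TestDiscoverMotif()._planted_windows(n=40)
        motif = discover_motif(windows, width=6, seed=0)
        p = motif_significance(motif, windows, n_permutations=99, seed=0)
        assert 0 < p <= 0.05

    def test_p_value_in_valid_range_on_noise(self):
        rng = np.random.default_rng(7)
        windows = ["".join(rng.choice(list("ACGT"), size=20)) for _ in range(40)]
        motif = discover_motif(windows, width=6, seed=0)
        p = motif_significance(motif, windows, n_permutations=99, seed=1)
        assert 0 < p <= 1
        assert p > 0.05  # shuffling composition-preserved noise changes nothing

    def test_too_few_permutations_rejected(self):
        motif = MotifModel(width=4, pfm=np.ones((4, 4)), background=np.full(4, 0.25))
        with pytest.raises(ValueError):
            motif_significance(motif, ["ACGTACGT"] * 5, n_permutations=10)


class TestSpacers:
    def test_hand_computed_spacer(self):
        # -10 site occupies offsets -12..-7 and -35 site -37..-32:
        # spacer = (-12) - (-32) - 1 = 19
        m10 = MotifModel(width=6, pfm=np.ones((6, 4)), background=np.full(4, 0.25),
                         sites=[(0, 8)])    # window starts at -20 -> -20+8 = -12
        m35 = MotifModel(width=6, pfm=np.ones((6, 4)), background=np.full(4, 0.25),
                         sites=[(0, 13)])   # window starts at -50 -> -50+13 = -37
        out = assign_minus35_and_spacers(m10, m35, n_tss=1)
        assert out["spacers"] == {0: 19}
        assert out["architecture"]["both"] == 1
        assert out["fraction_both"] == 1.0

    def test_architecture_partition_sums_to_n(self):
        m10 = MotifModel(width=6, pfm=np.ones((6, 4)), background=np.full(4, 0.25),
                         sites=[(0, 8), (2, 8)])
        m35 = MotifModel(width=6, pfm=np.ones((6, 4)), background=np.full(4, 0.25),
                         sites=[(0, 13), (3, 13)])
        out = assign_minus35_and_spacers(m10, m35, n_tss=5)
        assert sum(out["architecture"].values()) == 5
        assert out["architecture"] == {
            "both": 1, "minus10_only": 1, "minus35_only": 1, "neither": 2}
        assert out["fraction_minus10"] == pytest.approx(0.4)


class TestComposition:
    def test_hand_example(self):
        #      1234567
        seq = "AACTAGG"
        genome = _genome(seq)
        out = composition_at_tss([_tss(5)], genome)  # -1 = T, +1 = A
        assert out["pyrimidine_minus1"] == 1.0
        assert out["purine_plus1"] == 1.0
        # TSS at 3: -1 is position 2 (A, purine), +1 is position 3 (C, pyrimidine)
        out2 = composition_at_tss([_tss(3)], genome)
        assert out2["pyrimidine_minus1"] == 0.0
        assert out2["purine_plus1"] == 0.0

    def test_minus_strand_uses_transcript_orientation(self):
        #      12345
        seq = "AATGA"
        genome = _genome(seq)
        # TSS at 3 on -: +1 is complement of position 3 (T->A, purine),
        # -1 is complement of position 4 (G->C, pyrimidine)
        out = composition_at_tss([_tss(3, "-")], genome)
        assert out["pyrimidine_minus1"] == 1.0
        assert out["purine_plus1"] == 1.0

    def test_generator_biases_recovered(self):
        cfg = SimulationConfig(seed=11, genome_length=400_000, n_genes=200,
                               per_base_mutation_rate=0.0)
        genome, truth = generate_genome(cfg)
        tss = [_tss(t.position, t.strand) for t in truth.true_tss
               if t.tss_class in ("P", "S")]
        out = composition_at_tss(tss, genome)
        assert out["pyrimidine_minus1"] == pytest.approx(cfg.p_pyrimidine_minus1, abs=0.05)
        assert out["purine_plus1"] == pytest.approx(cfg.p_purine_plus1, abs=0.05)


class TestEndToEndPromoters:
    def test_planted_promoters_recovered_from_synthetic_genome(self):
        cfg = SimulationConfig(seed=5, per_base_mutation_rate=0.02,
                               p_minus35_present=1.0, p_secondary=0.0)
        genome, truth = generate_genome(cfg)
        primaries = [_tss(t.position, t.strand) for t in truth.true_tss
                     if t.tss_class == "P"]
        w10 = [extract_window(t, genome, -20, -1) for t in primaries]
        w35 = [extract_window(t, genome, -50, -21) for t in primaries]
        m10 = discover_motif(w10, width=6, seed=0)
        m35 = discover_motif(w35, width=6, seed=0)
        assert m10.consensus == cfg.minus10_consensus
        assert m35.consensus == cfg.minus35_consensus
        spac = assign_minus35_and_spacers(m10, m35, len(primaries))
        support = sum(v for k, v in spac["spacer_histogram"].items()
                      if k in cfg.spacer_dist)
        assert support / max(sum(spac["spacer_histogram"].values()), 1) >= 0.9


def test_encode_rejects_ambiguous_bases():
    with pytest.raises(ValueError, match="non-ACGT"):
        encode("ACGN")
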