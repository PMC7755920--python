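"""WW density, PWM scanning, rank-sum tests and logo matrices."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from promarch.io import reverse_complement
from promarch.motifs import (
    Pwm,
    best_tata_match,
    information_content_logo,
    load_tbp_pwm,
    pwm_relative_scores,
    ww_density,
    wilcoxon_rank_sum,
)


@pytest.fixture(scope="module")
def tbp():
    return load_tbp_pwm()


class TestPwm:
    def test_packaged_matrix_shape(self, tbp):
        assert len(tbp) == 15
        np.testing.assert_allclose(tbp.freq.sum(axis=0), 1.0)

    def test_jaspar_round_trip(self, tmp_path):
        text = ">M1 toy\nA [ 8 0 ]\nC [ 0 0 ]\nG [ 0 0 ]\nT [ 0 8 ]\n"
        p = tmp_path / "m.jaspar"
        p.write_text(text)
        pwm = Pwm.from_jaspar(str(p))
        assert pwm.consensus == "AT" and len(pwm) == 2


class TestPwmRelativeScores:
    def test_consensus_scores_100(self, tbp):
        assert pwm_relative_scores(tbp.consensus, tbp)[0] == pytest.approx(100.0)

    def test_anti_consensus_scores_0(self, tbp):
        assert pwm_relative_scores(tbp.anti_consensus, tbp)[0] == pytest.approx(0.0)

    def test_scores_bounded(self, tbp):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=60))
        s = pwm_relative_scores(seq, tbp)
        assert s.size == 60 - 15 + 1
        assert ((s >= 0) & (s <= 100)).all()

    def test_matches_brute_force_column_sum(self, tbp):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), size=16))
        got = pwm_relative_scores(seq, tbp)
        base_idx = {b: i for i, b in enumerate("ACGT")}
        smin, smax = tbp.log_odds.min(0).sum(), tbp.log_odds.max(0).sum()
        for start in range(2):
            s = sum(tbp.log_odds[base_idx[seq[start + k]], k] for k in range(15))
            expect = 100.0 * (s - smin) / (smax - smin)
            assert got[start] == pytest.approx(expect, abs=1e-9)

    def test_too_short_sequence_raises(self, tbp):
        with pytest.raises(ValueError):
            pwm_relative_scores("ACGT", tbp)

    def test_n_scores_as_background(self, tbp):
        # an all-N window scores the background expectation at every column
        s = pwm_relative_scores("N" * 15, tbp)[0]
        expect = 100.0 * (tbp._n_score.sum() - tbp._col_min.sum()) / (
            tbp._col_max.sum() - tbp._col_min.sum())
        assert s == pytest.approx(expect, abs=1e-9)


class TestWwDensity:
    def test_all_ww(self):
        prof = ww_density(["ATATAT"], [1])
        np.testing.assert_array_equal(prof.occurrence, [[1] * 5])

    def test_no_ww(self):
        prof = ww_density(["GCGCGC"], [1])
        np.testing.assert_array_equal(prof.occurrence, [[0] * 5])

    def test_rows_ordered_by_width(self):
        prof = ww_density(["ATATAT", "GCGCGC"], [10, 2])
        np.testing.assert_array_equal(prof.widths, [2, 10])
        np.testing.assert_array_equal(prof.occurrence[0], [0] * 5)

    def test_unequal_lengths_raise(self):
        with pytest.raises(ValueError):
            ww_density(["AT", "ATA"], [1, 2])

    def test_reverse_complement_mirror(self):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGT"), size=40))
        fwd = ww_density([seq], [1]).occurrence[0]
        rev = ww_density([reverse_complement(seq)], [1]).occurrence[0]
        np.testing.assert_array_equal(rev, fwd[::-1])


class TestBestTataMatch:
    GENOME = {"g": "G" * 200}

    def _clusters(self, dominant=100, strand="+"):
        return pd.DataFrame(
            [("TC0", "g", strand, dominant)],
            columns=["id", "chrom", "strand", "dominant_pos"],
        )

    def test_poly_g_window_is_near_minimal(self, tbp):
        best = best_tata_match(self._clusters(), self.GENOME, tbp)
        assert best.iloc[0] < 50.0

    def test_planted_consensus_scores_100(self, tbp):
        # a 15-mer fits the 16-base -35..-20 window starting at -35 or -34;
        # -35..-21 relative to the TSS at 100 are genomic 65..79
        g = list("G" * 200)
        g[64:79] = list(tbp.consensus)
        best = best_tata_match(self._clusters(), {"g": "".join(g)}, tbp)
        assert best.iloc[0] == pytest.approx(100.0)

    def test_planting_only_raises_score(self, tbp):
        rng = np.random.default_rng(3)
        seq = list(rng.choice(list("ACGT"), size=200))
        before = best_tata_match(self._clusters(), {"g": "".join(seq)}, tbp).iloc[0]
        seq[64:79] = list(tbp.consensus)  # valid start -35 inside the window
        after = best_tata_match(self._clusters(), {"g": "".join(seq)}, tbp).iloc[0]
        assert after >= before

    def test_minus_strand_uses_oriented_window(self, tbp):
        # -34..-20 on the minus strand at TSS 100 are genomic 134 down to
        # 120, so the plus-strand text 120..134 is the reverse complement
        g = list("G" * 200)
        g[119:134] = list(reverse_complement(tbp.consensus))
        best = best_tata_match(self._clusters(strand="-"), {"g": "".join(g)}, tbp)
        assert best.iloc[0] == pytest.approx(100.0)


class TestWilcoxon:
    def test_exact_small_sample(self):
        _, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_identical_samples_not_significant(self):
        _, p = wilcoxon_rank_sum([1, 2, 3, 4], [1, 2, 3, 4])
        assert p >= 0.9

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    def test_large_sample_agrees_with_scipy(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, 300)
        b = rng.normal(0.4, 1, 300)
        _, p = wilcoxon_rank_sum(a, b)
        _, p_ref = mannwhitneyu(a, b, alternative="two-sided")
        assert p == pytest.approx(p_ref, rel=0.10)


class TestInformationContent:
    def test_conserved_position_two_bits(self):
        logo = information_content_logo(["ACG", "ACG", "ACG"])
        np.testing.assert_allclose(logo["ic"], 2.0)

    def test_uniform_position_zero_bits(self):
        logo = information_content_logo(["A", "C", "G", "T"])
        assert logo["ic"].iloc[0] == pytest.approx(0.0)

    def test_hand_entropy(self):
        seqs = ["A"] * 7 + ["C", "G", "T"]
        logo = information_content_logo(seqs)
        assert logo["ic"].iloc[0] == pytest.approx(0.6432, abs=1e-4)
        assert logo["A"].iloc[0] == pytest.approx(0.7)

    def test_all_n_position_flagged(self):
        logo = information_content_logo(["NA", "NC"])
        assert logo["all_n"].iloc[0] and logo["ic"].iloc[0] == 0.0
        assert not logo["all_n"].iloc[1]

    def test_frequencies_sum_to_one(self):
        rng = np.random.default_rng(5)
        seqs = ["".join(rng.choice(list("ACGT"), size=10)) for _ in range(20)]
        logo = information_content_logo(seqs)
        np.testing.assert_allclose(logo[["A", "C", "G", "T"]].sum(axis=1), 1.0)
        assert ((logo["ic"] >= 0) & (logo["ic"] <= 2)).all()
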