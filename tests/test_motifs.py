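"""Background fitting, ZOOPS discovery, empirical E-values, motif
comparison and MEME/JASPAR I/O."""

import numpy as np
import pytest

from thymotif.motifs import (
    BackgroundModel,
    Pwm,
    compare_motifs,
    discover_motifs,
    fit_background,
    read_jaspar_pfm,
    read_meme,
    score_evalue,
    significance_threshold,
    subsample_sequences,
    write_meme,
)
from thymotif.sequences import dinucleotide_shuffle, decode, encode, revcomp

from conftest import PLANT, best_orientation_corr, planted_pwm_probs


class TestBackground:
    def test_alternating_sequence_dominates_conditionals(self):
        bg = fit_background(["AC" * 50], order=1)
        assert bg.cond[0, 1] > 0.9   # P(C | A)
        assert bg.cond[2, 3] > 0.9   # opposite strand: P(T | G)

    def test_uniform_random_input_near_quarter(self):
        rng = np.random.default_rng(0)
        seqs = ["".join(rng.choice(list("ACGT"), 2000)) for _ in range(20)]
        bg = fit_background(seqs, order=1)
        assert np.allclose(bg.cond, 0.25, atol=0.02)
        assert np.allclose(bg.freq0, 0.25, atol=0.02)

    def test_order0_homopolymer(self):
        bg = fit_background(["A" * 200], order=0)
        # both strands pooled: A and T share the mass
        assert bg.freq0[0] == pytest.approx(bg.freq0[3])
        assert bg.freq0[0] > 0.45

    def test_reverse_complement_symmetry(self):
        # both strands are pooled, so any word and its reverse complement
        # are (near-)equiprobable under the fitted model
        rng = np.random.default_rng(1)
        seqs = ["".join(rng.choice(list("ACGT"), p=[.4, .1, .2, .3], size=500))
                for _ in range(5)]
        bg = fit_background(seqs, order=1)
        w = 4
        lp = bg.word_logprobs(w)
        pows = 4 ** np.arange(w)
        idx = np.arange(4 ** w)
        digits = (idx[:, None] >> (2 * np.arange(w))) & 3
        rc = ((3 - digits[:, ::-1]) * pows).sum(axis=1)
        assert np.allclose(lp, lp[rc], atol=0.02)

    def test_word_logprobs_sum_to_one(self):
        bg = fit_background(["ACGTTGCA" * 30], order=1)
        for w in (2, 4):
            assert np.exp(bg.word_logprobs(w)).sum() == pytest.approx(1.0, abs=1e-9)
        # spot check against a hand chain: word "CA" = P(C)·P(A|C)
        lp = bg.word_logprobs(2)
        code_ca = 1 + 0 * 4
        assert lp[code_ca] == pytest.approx(
            np.log(bg.freq0[1]) + np.log(bg.cond[1, 0]), abs=1e-12
        )

    def test_too_little_data_errors(self):
        with pytest.raises(ValueError):
            fit_background(["ACGT"], order=1)


class TestSubsample:
    def test_identity_below_n(self):
        seqs = [f"s{i}" for i in range(500)]
        assert subsample_sequences(seqs, 600, seed=0) == seqs

    def test_deterministic_subset(self):
        seqs = [f"s{i}" for i in range(10_000)]
        a = subsample_sequences(seqs, 600, seed=3)
        b = subsample_sequences(seqs, 600, seed=3)
        assert a == b and len(a) == 600 and set(a) <= set(seqs)


class TestSignificanceThreshold:
    def test_trivial(self):
        assert significance_threshold(0.05, [1]) == 0.05

    def test_errors(self):
        with pytest.raises(ValueError):
            significance_threshold(0.0, [17])
        with pytest.raises(ValueError):
            significance_threshold(0.01, [0])


class TestDinucleotideShuffle:
    @pytest.mark.parametrize("seed", range(5))
    def test_preserves_doublet_counts_and_ends(self, seed):
        rng = np.random.default_rng(seed)
        seq = rng.integers(0, 4, size=300).astype(np.int8)
        out = dinucleotide_shuffle(seq, rng)
        assert out[0] == seq[0] and out[-1] == seq[-1]
        def doublets(codes):
            c = np.zeros((4, 4), dtype=int)
            np.add.at(c, (codes[:-1], codes[1:]), 1)
            return c
        assert np.array_equal(doublets(out), doublets(seq))

    def test_n_segments_shuffled_independently(self):
        rng = np.random.default_rng(0)
        seq = encode("ACGTACGTACGT" + "N" + "TTGGCCAATTGG")
        out = dinucleotide_shuffle(seq, rng)
        assert out[12] == 4 and len(out) == len(seq)
        assert sorted(out[:12]) == sorted(seq[:12])


class TestDiscovery:
    def test_planted_motif_recovered_as_top_hit(self, planted_motifs):
        top = planted_motifs[0]
        assert top.width == len(PLANT)
        corr = best_orientation_corr(top, planted_pwm_probs())
        assert corr > 0.9
        assert top.consensus in (PLANT, revcomp(PLANT))
        assert top.evalue == pytest.approx(1 / 51, rel=1e-6)

    def test_discovery_is_strand_symmetric(self, planted_seqs, planted_motifs):
        rc_seqs = [revcomp(s) for s in planted_seqs]
        bg = fit_background(rc_seqs, order=1)
        rc_motifs = discover_motifs(rc_seqs, bg, nmotifs=1, seed=5)
        a = planted_motifs[0].probs
        b = rc_motifs[0].reverse_complement().probs
        corr = max(
            best_orientation_corr(rc_motifs[0], a),
            best_orientation_corr(rc_motifs[0].reverse_complement(), a),
        )
        assert corr > 0.95

    def test_two_planted_motifs_both_recovered(self):
        rng = np.random.default_rng(9)
        second = "CCATATAAGGCC"
        seqs = []
        for _ in range(150):
            s = "".join(rng.choice(list("ACGT"), 120))
            for motif in (PLANT, second):
                if rng.random() < 0.6:
                    j = int(rng.integers(0, 120 - 12))
                    s = s[:j] + motif + s[j + 12 :]
            seqs.append(s)
        bg = fit_background(seqs, order=1)
        motifs = discover_motifs(seqs, bg, nmotifs=5, seed=2)
        found = set()
        for m in motifs[:5]:
            for name, cons in (("first", PLANT), ("second", second)):
                if best_orientation_corr(m, planted_pwm_probs(cons)) > 0.8:
                    found.add(name)
        assert found == {"first", "second"}

    def test_background_only_yields_no_confident_motif(self):
        floor_hits = total = 0
        for seed in range(3):
            rng = np.random.default_rng(100 + seed)
            seqs = ["".join(rng.choice(list("ACGT"), 100)) for _ in range(150)]
            bg = fit_background(seqs, order=1)
            motifs = discover_motifs(seqs, bg, nmotifs=3, seed=seed)
            for m in motifs:
                total += 1
                assert m.evalue >= 1 / 51 - 1e-12  # structural floor
                if m.evalue <= 1 / 51 + 1e-12:
                    floor_hits += 1
        # junk held-out p values are ~uniform; floor ties are rare
        assert floor_hits <= 2
        assert total >= 6

    def test_degenerate_input_flags_low_complexity(self):
        seqs = ["A" * 80 for _ in range(20)]
        bg = fit_background(seqs, order=1)
        motifs = discover_motifs(seqs, bg, nmotifs=5, seed=0)
        flagged = [m for m in motifs if m.meta.get("low_complexity")]
        assert len(flagged) <= 1
        assert len(motifs) <= 2

    def test_minimum_input_requirements(self):
        bg = BackgroundModel(0, np.full(4, 0.25))
        with pytest.raises(ValueError):
            discover_motifs(["ACGTACGTA"] * 5, bg)


class TestScoreEvalue:
    def test_deterministic_for_fixed_seed(self, planted_seqs, planted_motifs):
        bg = fit_background(planted_seqs, order=1)
        pwm = planted_motifs[0]
        a = score_evalue(pwm, planted_seqs[:60], bg, n_null=20, seed=11)
        b = score_evalue(pwm, planted_seqs[:60], bg, n_null=20, seed=11)
        assert a == b

    def test_floor_and_width_multiplier(self, planted_seqs, planted_motifs):
        bg = fit_background(planted_seqs, order=1)
        pwm = planted_motifs[0]
        e1 = score_evalue(pwm, planted_seqs[:60], bg, n_null=20, seed=1,
                          widths_examined=1)
        e3 = score_evalue(pwm, planted_seqs[:60], bg, n_null=20, seed=1,
                          widths_examined=3)
        assert e1 >= 1 / 21
        assert e3 == pytest.approx(3 * e1)

    def test_n_null_validation(self, planted_seqs, planted_motifs):
        bg = fit_background(planted_seqs, order=1)
        with pytest.raises(ValueError):
            score_evalue(planted_motifs[0], planted_seqs[:30], bg, n_null=0)
        with pytest.warns(UserWarning):
            score_evalue(planted_motifs[0], planted_seqs[:30], bg, n_null=5, seed=0)


class TestCompareMotifs:
    def rand_pwm(self, rng, w=8):
        p = np.clip(rng.dirichlet(np.ones(4), size=w).T, 1e-3, None)
        return Pwm(p / p.sum(axis=0, keepdims=True))

    def test_self_match_and_rc_symmetry(self):
        rng = np.random.default_rng(0)
        q = self.rand_pwm(rng)
        matches = compare_motifs(q, [q, q.reverse_complement()], n_perm=300, seed=1)
        assert matches[0].similarity == pytest.approx(1.0)
        assert matches[0].orientation == "+" and matches[0].offset == 0
        assert matches[1].similarity == pytest.approx(1.0)
        assert matches[1].orientation == "-"
        for m in matches:
            # at the permutation floor up to float near-ties in corrcoef
            assert m.p_value <= 3 / 301

    def test_bh_q_at_least_p_on_random_library(self):
        rng = np.random.default_rng(1)
        q = self.rand_pwm(rng, w=10)
        lib = [self.rand_pwm(rng, w=int(rng.integers(6, 14))) for _ in range(40)]
        matches = compare_motifs(q, lib, n_perm=100, seed=2)
        for m in matches:
            assert m.q_value >= m.p_value - 1e-12
            assert 0 < m.p_value <= 1 and 0 < m.q_value <= 1
        # p-values of unrelated motifs should spread broadly
        assert np.median([m.p_value for m in matches]) > 0.1

    def test_empty_library_errors(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError):
            compare_motifs(self.rand_pwm(rng), [])


class TestMotifIO:
    def test_meme_roundtrip(self, tmp_path, planted_motifs):
        p = tmp_path / "m.meme"
        write_meme(p, planted_motifs)
        back = read_meme(p)
        assert [m.name for m in back] == [m.name for m in planted_motifs]
        for a, b in zip(back, planted_motifs):
            assert np.allclose(a.probs, b.probs, atol=2e-5)
            assert a.evalue == pytest.approx(b.evalue, rel=0.01)
            assert a.nsites == b.nsites

    def test_small_probabilities_survive_roundtrip(self, tmp_path):
        probs = np.full((4, 6), 0.001)
        probs[0] = 0.997
        pwm = Pwm(probs / probs.sum(axis=0, keepdims=True), name="sharp", nsites=28)
        p = tmp_path / "m.meme"
        write_meme(p, [pwm])
        back = read_meme(p)[0]
        assert back.probs.min() > 5e-4  # not quantized away

    def test_jaspar_pfm(self, tmp_path):
        p = tmp_path / "m.pfm"
        p.write_text(
            ">MA0001.1 TEST\n"
            "A [ 10  0  5 ]\n"
            "C [  0 10  5 ]\n"
            "G [  0  0  0 ]\n"
            "T [  0  0  0 ]\n"
        )
        (pwm,) = read_jaspar_pfm(p)
        assert pwm.width == 3
        assert pwm.probs[0, 0] > 0.7  # counts + pseudocount, normalized
        assert np.allclose(pwm.probs.sum(axis=0), 1.0)
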