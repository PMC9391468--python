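"""Variant normalization, allele sequence construction and exact-null
PWM scanning."""

from itertools import product

import numpy as np
import pytest

from thymotif.motifs import BackgroundModel, Pwm
from thymotif.scan import (
    AllelePair,
    ScoreTable,
    Variant,
    VariantError,
    best_hit,
    extract_allele_sequences,
    log_odds,
    normalize_variant,
    read_dash_table,
    read_scan_table,
    read_vcf,
    scan_variants,
    write_scan_table,
)
from thymotif.sequences import revcomp

UNIFORM_BG = BackgroundModel(0, np.full(4, 0.25))


def sharp_pwm(consensus: str, match: float = 0.925) -> Pwm:
    probs = np.full((4, len(consensus)), (1 - match) / 3)
    for i, b in enumerate(consensus):
        probs["ACGT".index(b), i] = match
    return Pwm(probs, name="sharp")


class TestNormalizeVariant:
    def test_vcf_anchor_trim(self):
        # VCF 1-based pos 102 with REF=A ALT=AG is a G insertion at 0-based 102
        v = normalize_variant("chr1", 101, "A", "AG", "rs1")
        assert (v.pos, v.ref_allele, v.alt_allele) == (102, "", "G")

    def test_dash_form(self):
        v = normalize_variant("chr1", 50, "-", "G", "rs138300818")
        assert (v.pos, v.ref_allele, v.alt_allele) == (50, "", "G")
        assert (v.dash_ref, v.dash_alt) == ("-", "G")

    def test_null_variant_errors(self):
        with pytest.raises(VariantError):
            normalize_variant("chr1", 10, "ACG", "ACG")

    def test_non_acgt_errors(self):
        with pytest.raises(VariantError):
            normalize_variant("chr1", 10, "AXG", "A")

    def test_suffix_and_prefix_trim(self):
        v = normalize_variant("chr1", 10, "CAC", "CGC")
        assert (v.pos, v.ref_allele, v.alt_allele) == (11, "A", "G")


class TestAlleleSequences:
    def test_insertion_lengths(self, tiny_genome):
        v = Variant("chr1", 100, "", "G", "ins1")
        pair = extract_allele_sequences(v, tiny_genome, flank=30)
        assert len(pair.seq_ref) == 60 and len(pair.seq_alt) == 61

    def test_12bp_deletion_lengths(self, tiny_genome):
        ref = tiny_genome["chr1"][100:112]
        v = Variant("chr1", 100, ref, "", "del12")
        pair = extract_allele_sequences(v, tiny_genome, flank=30)
        assert len(pair.seq_ref) == 72 and len(pair.seq_alt) == 60

    def test_snv_differs_at_one_position(self, tiny_genome):
        ref = tiny_genome["chr1"][100]
        alt = "ACGT"["ACGT".index(ref) - 1]
        pair = extract_allele_sequences(Variant("chr1", 100, ref, alt, "s"), tiny_genome)
        diffs = [i for i, (a, b) in enumerate(zip(pair.seq_ref, pair.seq_alt)) if a != b]
        assert diffs == [30]

    def test_shared_flank_identity(self, tiny_genome):
        rng = np.random.default_rng(0)
        for _ in range(20):
            pos = int(rng.integers(40, 400))
            kind = rng.choice(["snv", "ins", "del"])
            if kind == "snv":
                ref = tiny_genome["chr1"][pos]
                alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
            elif kind == "ins":
                ref, alt = "", "".join(rng.choice(list("ACGT"), 3))
            else:
                ref, alt = tiny_genome["chr1"][pos : pos + 4], ""
            v = Variant("chr1", pos, ref, alt, "x")
            pair = extract_allele_sequences(v, tiny_genome)
            rebuilt = pair.seq_ref[:30] + v.alt_allele + pair.seq_ref[
                len(pair.seq_ref) - 30 :
            ]
            assert rebuilt == pair.seq_alt

    def test_reference_mismatch_names_variant(self, tiny_genome):
        base = tiny_genome["chr1"][100]
        wrong = "ACGT"[("ACGT".index(base) + 1) % 4]
        with pytest.raises(VariantError, match="badref"):
            extract_allele_sequences(Variant("chr1", 100, wrong, "", "badref"),
                                     tiny_genome)

    def test_flank_mismatch_rejected_by_invariant(self):
        with pytest.raises(VariantError, match="flank"):
            AllelePair(Variant("chr1", 50, "A", "C", "x"),
                       "A" * 30 + "A" + "G" * 30,
                       "C" * 30 + "C" + "G" * 30)


class TestLogOdds:
    def test_background_column_scores_zero(self):
        pwm = Pwm(np.full((4, 3), 0.25))
        assert np.allclose(log_odds(pwm, UNIFORM_BG), 0.0)

    def test_doubling_probability_adds_one_bit(self):
        p = np.full((4, 2), 0.2)
        p[0, 0] = 0.4
        pwm = Pwm(p / p.sum(axis=0, keepdims=True))
        lo = log_odds(pwm, UNIFORM_BG)
        p2 = p.copy()
        p2[0, 0] = 0.8
        p2[1:, 0] = 0.4 / 6  # halve the rest to keep the column a distribution
        # direct log law: log2(2x/bg) - log2(x/bg) = 1
        assert np.log2(0.4 / 0.25) - np.log2(0.2 / 0.25) == pytest.approx(1.0)
        assert lo[0, 0] - lo[1, 0] == pytest.approx(1.0)

    def test_order1_background_rejected(self):
        pwm = Pwm(np.full((4, 3), 0.25))
        bg1 = BackgroundModel(1, np.full(4, 0.25), np.full((4, 4), 0.25))
        with pytest.raises(ValueError):
            log_odds(pwm, bg1)


class TestScoreTable:
    def test_uniform_pwm_degenerate(self):
        pwm = Pwm(np.full((4, 2), 0.25))
        t = ScoreTable(pwm, UNIFORM_BG)
        assert t.p_for_int(0) == 1.0

    def test_enumeration_equality_small_widths(self):
        rng = np.random.default_rng(0)
        for w in (2, 3, 4):
            p = np.clip(rng.dirichlet(np.ones(4) * 0.7, size=w).T, 1e-3, None)
            pwm = Pwm(p / p.sum(axis=0, keepdims=True))
            bg = BackgroundModel(0, np.array([0.3, 0.2, 0.2, 0.3]))
            t = ScoreTable(pwm, bg, resolution=400)
            tail = {}
            for word in product(range(4), repeat=w):
                ti = int(sum(t.int_matrix[b, i] for i, b in enumerate(word)))
                pr = float(np.prod([bg.freq0[b] for b in word]))
                tail[ti] = tail.get(ti, 0.0) + pr
            acc = 0.0
            for ti in sorted(tail, reverse=True):
                acc += tail[ti]
                assert t.p_for_int(ti) == pytest.approx(acc, abs=1e-12)

    def test_max_score_probability_closed_form(self):
        pwm = sharp_pwm("ACGT")
        bg = BackgroundModel(0, np.array([0.4, 0.1, 0.2, 0.3]))
        t = ScoreTable(pwm, bg)
        tmax = int(t.int_matrix.max(axis=0).sum())
        # unique best base per column: P(max) = prod of their bg freqs
        expect = 0.4 * 0.1 * 0.2 * 0.3
        assert t.p_for_int(tmax) == pytest.approx(expect, rel=1e-9)

    def test_resolution_validation(self):
        with pytest.raises(ValueError):
            ScoreTable(sharp_pwm("ACGT"), UNIFORM_BG, resolution=10)


class TestBestHit:
    def test_planted_consensus_is_best_hit(self):
        pwm = sharp_pwm("TGACGTCA")
        rng = np.random.default_rng(1)
        bgseq = "".join(rng.choice(list("ACGT"), 60))
        seq = bgseq[:25] + "TGACGTCA" + bgseq[25:]
        hit = best_hit(pwm, seq, UNIFORM_BG)
        assert hit.offset == 25 and hit.strand == "+"
        table = ScoreTable(pwm, UNIFORM_BG)
        assert hit.score == pytest.approx(float(table.lo.max(axis=0).sum()))

    def test_reverse_complement_invariance(self):
        pwm = sharp_pwm("TGACGTCA")
        rng = np.random.default_rng(2)
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), 80))
            a = best_hit(pwm, seq, UNIFORM_BG)
            b = best_hit(pwm, revcomp(seq), UNIFORM_BG)
            assert a.score == pytest.approx(b.score)
            assert a.p_value == pytest.approx(b.p_value)

    def test_n_windows_skipped(self):
        pwm = sharp_pwm("ACGT")
        seq = "ACGT" + "N" + "TTTTTTT"
        hit = best_hit(pwm, seq, UNIFORM_BG)
        assert hit.offset == 0  # windows crossing the N are excluded

    def test_short_sequence_sentinel(self):
        pwm = sharp_pwm("ACGTACGT")
        hit = best_hit(pwm, "ACG", UNIFORM_BG)
        assert hit.score == float("-inf") and hit.p_value == 1.0

    def test_window_pvalues_are_conservative(self):
        """Exact-null per-window p-values are super-uniform under the
        background at every tested threshold."""
        pwm = sharp_pwm("TGACGTCATG", match=0.8)
        bg = BackgroundModel(0, np.array([0.3, 0.2, 0.2, 0.3]))
        t = ScoreTable(pwm, bg)
        rng = np.random.default_rng(3)
        n = 10_000
        draws = rng.choice(4, size=(n, pwm.width), p=bg.freq0)
        ints = t.int_matrix[draws, np.arange(pwm.width)].sum(axis=1)
        pvals = np.array([t.p_for_int(ti) for ti in ints])
        for alpha in (0.05, 0.01, 0.001):
            frac = float(np.mean(pvals < alpha))
            assert frac <= alpha + 3 * np.sqrt(alpha / n)


class TestScanVariants:
    def make_pairs(self, genome, n):
        rng = np.random.default_rng(4)
        pairs = []
        for i in range(n):
            pos = 40 + i * 7
            ref = genome["chr1"][pos]
            alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
            v = Variant("chr1", pos, ref, alt, f"v{i}")
            pairs.append(extract_allele_sequences(v, genome))
        return pairs

    def test_cardinality(self, tiny_genome):
        pairs = self.make_pairs(tiny_genome, 10)
        motifs = {"ds1": [sharp_pwm("ACGTAC"), sharp_pwm("TTGGCC")],
                  "ds2": [sharp_pwm("GATTAC")]}
        bgs = {"ds1": UNIFORM_BG, "ds2": UNIFORM_BG}
        results = scan_variants(pairs, motifs, bgs)
        assert len(results) == 10 * 3

    def test_variant_far_from_site_scores_identically(self, tiny_genome):
        # plant the motif consensus well upstream of the variant so the
        # best hit falls in the shared flank
        genome = dict(tiny_genome)
        genome["chr1"] = genome["chr1"][:60] + "TGACGTCATTGG" + genome["chr1"][72:]
        pos = 120
        ref = genome["chr1"][pos]
        alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
        v = Variant("chr1", pos, ref, alt, "far")
        pair = extract_allele_sequences(v, genome)
        pwm = sharp_pwm("TGACGTCATTGG")
        a = best_hit(pwm, pair.seq_ref, UNIFORM_BG)
        b = best_hit(pwm, pair.seq_alt, UNIFORM_BG)
        # no strong hit inside the window: scores equal on shared flanks
        assert a.score == pytest.approx(b.score)
        assert a.p_value == pytest.approx(b.p_value)


class TestVariantIO:
    def test_vcf_reader(self, tmp_path):
        p = tmp_path / "v.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t101\trs1\tA\tC\t.\tPASS\t.\n"
            "chr1\t200\trs2\tG\tGTT\t.\tPASS\t.\n"
        )
        vs = read_vcf(p)
        assert (vs[0].chrom, vs[0].pos, vs[0].ref_allele, vs[0].alt_allele) == (
            "chr1", 100, "A", "C")
        assert (vs[1].pos, vs[1].ref_allele, vs[1].alt_allele) == (200, "", "TT")

    def test_dash_table_reader(self, tmp_path):
        p = tmp_path / "v.tsv"
        p.write_text(
            "id\tchrom\tpos\tref\talt\n"
            "rs138300818\tchr6\t1000\t-\tG\n"
        )
        (v,) = read_dash_table(p)
        assert (v.ref_allele, v.alt_allele, v.pos) == ("", "G", 1000)

    def test_scan_table_roundtrip(self, tmp_path, tiny_genome):
        pairs = TestScanVariants().make_pairs(tiny_genome, 4)
        results = scan_variants(pairs, {"ds": [sharp_pwm("ACGTAC")]},
                                {"ds": UNIFORM_BG})
        p = tmp_path / "scan.tsv"
        write_scan_table(p, results)
        back = read_scan_table(p)
        assert len(back) == len(results)
        for a, b in zip(back, results):
            assert a.variant_id == b.variant_id
            assert a.sc_ref == pytest.approx(b.sc_ref, abs=1e-3)
            assert a.significant_overlap == b.significant_overlap
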