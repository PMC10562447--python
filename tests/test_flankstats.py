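import functools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seedflank.flankstats import (PWM, DiversityProfile, combined_promoter_pwm,
                                  diversity_profile, dna_shape, edit_distance,
                                  kmer_correlation, kmer_frequencies,
                                  load_shape_table, packaged_shape_table,
                                  pwm_log_odds, pwm_pvalue, read_jaspar,
                                  read_meme_minimal, scan_pwm,
                                  second_promoter_scan, shape_embedding,
                                  synthetic_shape_table, template_difference)
from seedflank.seqcore import SeedSpec, reverse_complement

from conftest import random_seq

dna = st.text(alphabet="ACGT", max_size=12)


# ---------------------------------------------------------------------------
# k-mers

class TestKmers:
    def test_single_kmer(self):
        f = kmer_frequencies(["AAAA"], 4)
        assert f[0] == 1.0 and f.sum() == 1.0 and (f[1:] == 0).all()

    def test_probability_vector(self, rng):
        seqs = [random_seq(rng, 40) for _ in range(20)]
        f = kmer_frequencies(seqs, 4)
        assert (f >= 0).all()
        assert f.sum() == pytest.approx(1.0, abs=1e-12)

    def test_hashmap_recount_oracle(self, rng):
        seqs = [random_seq(rng, 165) for _ in range(50)]
        f = kmer_frequencies(seqs, 4)
        counts = {}
        for s in seqs:
            for i in range(len(s) - 3):
                counts[s[i:i + 4]] = counts.get(s[i:i + 4], 0) + 1
        total = sum(counts.values())
        for kmer, c in counts.items():
            idx = functools.reduce(lambda a, ch: a * 4 + "ACGT".index(ch), kmer, 0)
            assert f[idx] == pytest.approx(c / total, rel=1e-12)

    def test_region_restriction(self):
        # distal half is all A, proximal all C
        f_d = kmer_frequencies(["AAAAACCCCC"], 2, region="distal")
        f_p = kmer_frequencies(["AAAAACCCCC"], 2, region="proximal")
        assert f_d[0] == 1.0          # AA
        assert f_p[1 * 4 + 1] == 1.0  # CC

    def test_short_sequences_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="skipped"):
            f = kmer_frequencies(["AC", "ACGTACGT"], 4)
        assert f.sum() == pytest.approx(1.0)

    def test_self_correlation_is_one(self, rng):
        seqs = [random_seq(rng, 60) for _ in range(10)]
        assert kmer_correlation(seqs, seqs, 4) == pytest.approx(1.0)

    def test_disjoint_kmer_sets_anticorrelate(self):
        assert kmer_correlation(["A" * 30], ["C" * 30], 4) < 0

    def test_sets_with_shared_composition_correlate(self, rng):
        """Two independent samples from the same biased background share
        their k-mer spectrum structure, so r is high; under a uniform
        background the centered spectra are pure sampling noise and r ~ 0."""
        p = np.array([0.4, 0.1, 0.1, 0.4])
        def draw(n):
            return ["".join("ACGT"[i] for i in rng.choice(4, size=165, p=p))
                    for _ in range(n)]
        assert kmer_correlation(draw(500), draw(500), 4) > 0.9

    def test_zero_variance_error(self):
        with pytest.raises(ValueError, match="undefined|zero-variance"):
            kmer_correlation(["ACGT" * 5], ["A"], 1)


# ---------------------------------------------------------------------------
# edit distance and diversity

def _brute_ed(a, b):
    @functools.lru_cache(maxsize=None)
    def rec(i, j):
        if i == 0:
            return j
        if j == 0:
            return i
        return min(rec(i - 1, j) + 1, rec(i, j - 1) + 1,
                   rec(i - 1, j - 1) + (a[i - 1] != b[j - 1]))
    return rec(len(a), len(b))


class TestEditDistance:
    def test_identity_and_empty(self):
        assert edit_distance("ACGT", "ACGT") == 0
        assert edit_distance("", "ACGT") == 4
        assert edit_distance("", "") == 0

    def test_brute_force_recursion_oracle(self, rng):
        for _ in range(200):
            a = random_seq(rng, int(rng.integers(0, 9)))
            b = random_seq(rng, int(rng.integers(0, 9)))
            assert edit_distance(a, b) == _brute_ed(a, b)

    @given(dna, dna, dna)
    @settings(max_examples=60, deadline=None)
    def test_metric_axioms(self, a, b, c):
        assert edit_distance(a, b) == edit_distance(b, a)
        assert (edit_distance(a, b) == 0) == (a == b)
        assert edit_distance(a, c) <= edit_distance(a, b) + edit_distance(b, c)


class TestDiversityProfile:
    def test_single_pair(self):
        prof = diversity_profile(["ACGT"], {"g": ["ACGT"]})
        assert list(prof.distances["g"]) == [0]

    def test_cardinality(self, rng):
        prof = diversity_profile([random_seq(rng, 10) for _ in range(3)],
                                 {"n": [random_seq(rng, 10) for _ in range(4)]})
        assert len(prof.distances["n"]) == 12

    def test_histogram_matches_pairwise_recount(self, rng):
        a = [random_seq(rng, 20) for _ in range(10)]
        b = [random_seq(rng, 20) for _ in range(10)]
        prof = diversity_profile(a, {"g": b})
        recount = sorted(edit_distance(x, y) for x in a for y in b)
        assert sorted(prof.distances["g"]) == recount


class TestTemplateDifference:
    def test_identical_is_zero(self):
        spec = SeedSpec(16, (("TATAAT", 5),))
        t = spec.apply_to("A" * 16)
        td = template_difference([t], t, spec)
        assert td.scores[0] == 0.0 and td.sd == 0.0

    def test_hand_computable_flanking_mode(self):
        spec = SeedSpec(16, (("TATAAT", 5),))
        template = spec.apply_to("A" * 16)
        designed = spec.apply_to("C" * 16)
        td = template_difference([designed], template, spec, mode="flanking")
        # flanks: 10 all-A vs all-C positions -> ed 10, flanking length 10
        assert td.scores[0] == pytest.approx(1.0)

    def test_levenshtein_not_above_hamming(self, rng):
        """Control-2 style: random flanks vs fixed template; the
        Levenshtein-based score never exceeds the Hamming-based one and the
        expected mismatch fraction stays <= 0.75."""
        spec = SeedSpec(60, (("TTGACA", 10), ("TATAAT", 33)))
        template = spec.apply_to(random_seq(np.random.default_rng(0), 60))
        designs = [spec.apply_to(random_seq(rng, 60)) for _ in range(40)]
        td = template_difference(designs, template, spec, mode="flanking")
        mask = spec.seed_mask
        for seq, s in zip(designs, td.scores):
            hamming = sum(c1 != c2 for c1, c2, m in zip(seq, template, mask)
                          if not m)
            assert s <= hamming / 48 + 1e-12
        assert td.mean <= 0.75 + 3 * td.sd / np.sqrt(len(designs))

    def test_mode_validation(self):
        spec = SeedSpec(16, (("TATAAT", 5),))
        with pytest.raises(ValueError):
            template_difference(["A" * 16], "A" * 16, spec, mode="bogus")


# ---------------------------------------------------------------------------
# PWMs

class TestPWMScoring:
    def test_uniform_pwm_scores_zero(self, rng):
        pwm = PWM(np.full((6, 4), 0.25), pseudocount=0.0)
        for _ in range(5):
            assert pwm_log_odds(random_seq(rng, 6), pwm) == pytest.approx(0.0)

    def test_consensus_attains_max(self, rng):
        mat = np.random.default_rng(4).dirichlet(np.ones(4), size=8)
        pwm = PWM(mat)
        best = pwm_log_odds(pwm.consensus, pwm)
        for _ in range(50):
            assert pwm_log_odds(random_seq(rng, 8), pwm) <= best + 1e-12

    def test_straight_loop_oracle(self, rng):
        for trial in range(10):
            mat = np.random.default_rng(trial).dirichlet(np.ones(4), size=8)
            pwm = PWM(mat)
            w = random_seq(rng, 8)
            padj = (mat + pwm.pseudocount) / (1 + 4 * pwm.pseudocount)
            expected = sum(np.log2(padj[i, "ACGT".index(c)] / 0.25)
                           for i, c in enumerate(w))
            assert pwm_log_odds(w, pwm) == pytest.approx(expected, rel=1e-12)

    def test_scan_minus_strand(self):
        pwm = PWM.from_consensus("TTGACA", major=0.97)
        seq = "C" * 10 + reverse_complement("TTGACA") + "C" * 10
        scores = scan_pwm(seq, pwm, both_strands=True)
        assert scores["-"].argmax() == 10
        assert scores["-"].max() > scores["+"].max()

    def test_width_mismatch(self):
        with pytest.raises(ValueError):
            pwm_log_odds("ACGT", PWM.from_consensus("TTGACA"))


class TestPWMPvalue:
    def test_extremes(self):
        pwm = PWM.from_consensus("TATAAT")
        assert pwm_pvalue(pwm, -np.inf) == 1.0
        max_score = pwm.log_odds.max(axis=1).sum()
        assert pwm_pvalue(pwm, max_score + 1.0) == 0.0

    def test_exhaustive_enumeration_width4(self):
        """DP matches summing background probabilities of all 256 4-mers,
        discretized the same way."""
        rng = np.random.default_rng(8)
        mat = rng.dirichlet(np.ones(4) * 2, size=4)
        bg = rng.dirichlet(np.ones(4) * 20)
        pwm = PWM(mat, background=bg)
        lo = pwm.log_odds
        delta = 1e-3
        words = []
        for w in range(256):
            idx = [(w >> (2 * i)) & 3 for i in range(4)]
            iscore = sum(int(np.floor(lo[i, b] / delta)) for i, b in enumerate(idx))
            prob = np.prod([bg[b] for b in idx])
            words.append((iscore, prob))
        for q in np.linspace(lo.min() * 4, lo.max(axis=1).sum(), 23):
            target = int(np.floor(q / delta))
            expected = sum(p for s, p in words if s >= target)
            assert pwm_pvalue(pwm, q) == pytest.approx(expected, abs=1e-6)

    def test_monotone_nonincreasing(self):
        pwm = PWM.from_consensus("TTGACA", major=0.8)
        scores = np.linspace(-10, 12, 40)
        ps = [pwm_pvalue(pwm, s) for s in scores]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))

    def test_nonfinite_score_rejected(self):
        with pytest.raises(ValueError):
            pwm_pvalue(PWM.from_consensus("TATAAT"), np.nan)


class TestSecondPromoterScan:
    def test_planted_consensus_is_global_minimum(self, rng):
        p10 = PWM.from_consensus("TATAAT", major=0.9)
        p35 = PWM.from_consensus("TTGACA", major=0.9)
        seq = list(random_seq(rng, 120))
        seq[40:46] = "TTGACA"
        seq[63:69] = "TATAAT"  # 17 bp spacer
        offsets, pvals, flagged = second_promoter_scan("".join(seq), p10, p35)
        assert offsets[np.argmin(pvals)] == 40
        assert flagged

    def test_random_sequence_not_flagged_at_stringent_threshold(self):
        seq = random_seq(np.random.default_rng(123), 150)
        _, _, flagged = second_promoter_scan(
            seq, PWM.from_consensus("TATAAT", major=0.9),
            PWM.from_consensus("TTGACA", major=0.9), significance=1e-6)
        assert not flagged

    def test_exclusion_of_original_region(self, rng):
        p10 = PWM.from_consensus("TATAAT", major=0.9)
        p35 = PWM.from_consensus("TTGACA", major=0.9)
        seq = list(random_seq(rng, 120))
        seq[40:46] = "TTGACA"
        seq[63:69] = "TATAAT"
        _, pvals, flagged = second_promoter_scan(
            "".join(seq), p10, p35, significance=1e-6, exclude=(40, 69))
        assert pwm_pvalue(combined_promoter_pwm(p35, p10), 0) > 0  # sanity
        assert not flagged  # only hit overlaps the original promoter

    def test_spacer_columns_contribute_zero(self):
        p10 = PWM.from_consensus("TATAAT", major=0.9)
        p35 = PWM.from_consensus("TTGACA", major=0.9)
        combined = combined_promoter_pwm(p35, p10, spacer_bp=17)
        seq = "TTGACA" + "A" * 17 + "TATAAT"
        expected = pwm_log_odds("TTGACA", p35) + pwm_log_odds("TATAAT", p10)
        assert pwm_log_odds(seq, combined) == pytest.approx(expected, abs=1e-9)

    def test_too_wide_raises(self):
        with pytest.raises(ValueError, match="wider"):
            second_promoter_scan("ACGTACGT", PWM.from_consensus("TATAAT"),
                                 PWM.from_consensus("TTGACA"))


def test_motif_file_readers(tmp_path):
    jaspar = tmp_path / "m.jaspar"
    jaspar.write_text(">MA0001.1 test\nA [ 3 10  2 ]\nC [ 5  2  1 ]\n"
                      "G [ 1  1 12 ]\nT [ 6  2  0 ]\n")
    (pwm,) = read_jaspar(jaspar)
    assert pwm.width == 3
    np.testing.assert_allclose(pwm.matrix.sum(axis=1), 1.0)
    meme = tmp_path / "m.meme"
    meme.write_text("MEME version 4\n\nALPHABET= ACGT\n\nMOTIF crp\n"
                    "letter-probability matrix: alength= 4 w= 2\n"
                    "0.1 0.2 0.3 0.4\n0.25 0.25 0.25 0.25\n\n")
    (pwm2,) = read_meme_minimal(meme)
    assert pwm2.width == 2 and pwm2.name == "crp"


# ---------------------------------------------------------------------------
# DNA shape

@pytest.fixture(scope="module")
def shape_table():
    return synthetic_shape_table()


class TestDNAShape:
    def test_homopolymer_constant_interior(self, shape_table):
        tr = dna_shape("A" * 7, shape_table)
        aaaaa = shape_table["AAAAA"]
        np.testing.assert_allclose(tr.mgw[2:5], aaaaa[0])
        np.testing.assert_allclose(tr.prot[2:5], aaaaa[1])

    def test_defined_spans(self, shape_table, rng):
        seq = random_seq(rng, 30)
        tr = dna_shape(seq, shape_table)
        assert tr.defined("mgw").sum() == 26  # L - 4
        assert tr.defined("roll").sum() == 26
        assert tr.defined("helt").sum() == 26

    def test_mgw_prot_rc_symmetry(self, shape_table, rng):
        for _ in range(50):
            seq = random_seq(rng, 25)
            fwd = dna_shape(seq, shape_table)
            rev = dna_shape(reverse_complement(seq), shape_table)
            np.testing.assert_allclose(fwd.mgw[2:-2], rev.mgw[2:-2][::-1])
            np.testing.assert_allclose(fwd.prot[2:-2], rev.prot[2:-2][::-1])

    def test_roll_helt_orientation_rule(self, shape_table, rng):
        """Interior steps (double-contribution) of the reverse complement
        mirror the forward steps: step i maps to step L-2-i."""
        for _ in range(20):
            seq = random_seq(rng, 25)
            L = len(seq)
            fwd = dna_shape(seq, shape_table)
            rev = dna_shape(reverse_complement(seq), shape_table)
            for i in range(2, L - 4):   # both-contribution steps
                j = L - 2 - i
                if 2 <= j <= L - 4:
                    assert fwd.roll[i] == pytest.approx(rev.roll[j], abs=1e-9)
                    assert fwd.helt[i] == pytest.approx(rev.helt[j], abs=1e-9)

    def test_missing_pentamer_raises(self):
        with pytest.raises(KeyError, match="AAAAA"):
            dna_shape("AAAAAAA", {})

    def test_packaged_table_matches_generator(self, shape_table):
        assert packaged_shape_table() == {k: tuple(v)
                                          for k, v in shape_table.items()}


class TestShapeEmbedding:
    def test_duplicates_land_together(self, shape_table, rng):
        seqs = [random_seq(rng, 20) for _ in range(10)]
        emb = shape_embedding(seqs + seqs, shape_table, reduction_seed=0,
                              method="pca")
        n = len(seqs)
        diam = np.ptp(emb, axis=0).max()
        for i in range(n):
            d = np.linalg.norm(emb[i] - emb[n + i])
            assert d < 0.01 * max(diam, 1e-9)

    def test_at_shifted_populations_separate(self, shape_table):
        rng = np.random.default_rng(5)
        def biased(p_at, n):
            return ["".join(rng.choice(list("AT")) if rng.random() < p_at
                            else rng.choice(list("GC")) for _ in range(24))
                    for _ in range(n)]
        a, b = biased(0.85, 20), biased(0.15, 20)
        emb = shape_embedding(a + b, shape_table, reduction_seed=0)
        from sklearn.metrics import silhouette_score
        labels = [0] * 20 + [1] * 20
        assert silhouette_score(emb, labels) > 0.2

    def test_seeded_determinism(self, shape_table, rng):
        seqs = [random_seq(rng, 20) for _ in range(15)]
        e1 = shape_embedding(seqs, shape_table, reduction_seed=3)
        e2 = shape_embedding(seqs, shape_table, reduction_seed=3)
        np.testing.assert_array_equal(e1, e2)

    def test_unequal_lengths_rejected(self, shape_table):
        with pytest.raises(ValueError, match="length"):
            shape_embedding(["A" * 20] * 9 + ["A" * 21], shape_table)
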