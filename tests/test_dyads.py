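"""Spaced-dyad discovery: arm detection, enumeration, significance, EM."""

import math

import numpy as np
import pytest
from scipy.special import comb

import synregulon as sr
from synregulon.dyads import (
    _mismatch_neighbourhood,
    _neighbourhood_prob,
    candidate_arm_words,
    hamming,
    promoter_base_frequencies,
)


def _promoter(seq, pid="p"):
    return sr.Promoter(pid, seq, "x", (0, len(seq)), "+")


class TestFindArms:
    def test_three_at_rich_arms_in_consensus(self, consensus36):
        occ = sr.find_arms(consensus36, {"AATTTT", "AAAATT"})
        assert [(o.offset, o.word) for o in occ] == [
            (0, "AATTTT"),
            (9, "AAAATT"),
            (30, "AATTTT"),
        ]

    def test_gc_only_sequence_empty(self):
        assert sr.find_arms("GGGGGGGG", {"AATTTT"}) == []

    def test_tandem_overlap_reported(self):
        occ = sr.find_arms("AATTTTAATTTT", {"AATTTT"})
        # exact-word occurrences at 0 and 6; the junction windows are
        # reverse-complement matches (TTAATT etc.) only if they equal AAAATT
        exact = [o.offset for o in occ if o.word == "AATTTT"]
        assert exact == [0, 6]

    def test_reverse_sense_labelled(self):
        occ = sr.find_arms("AAAATT", {"AATTTT"})
        assert len(occ) == 1 and occ[0].sense == "reverse-arm"

    def test_mixed_word_lengths_rejected(self):
        with pytest.raises(ValueError):
            sr.find_arms("ACGT", {"AAT", "AATT"})


class TestPairArms:
    def test_consensus_has_two_palindromic_pairs(self, consensus36):
        occ = sr.find_arms(consensus36, {"AATTTT", "AAAATT"})
        pairs = sr.pair_arms(occ)
        assert [(p.left.offset, p.right.offset, p.spacer) for p in pairs] == [
            (0, 9, 3),
            (9, 30, 15),
        ]

    def test_outer_pair_spacer_fifteen(self, consensus36):
        pairs = sr.pair_arms(sr.find_arms(consensus36, {"AATTTT", "AAAATT"}))
        outer = max(pairs, key=lambda p: p.span)
        assert outer.spacer == 15

    def test_overlapping_occurrences_not_paired(self):
        occ = sr.find_arms("AATTTTTT", {"AATTTT"})  # AATTTT@0 overlaps rc word?
        pairs = sr.pair_arms(occ)
        for p in pairs:
            assert p.right.offset >= p.left.offset + 6


class TestEnumerate:
    def test_consensus_contains_both_reported_dyads(self, consensus36):
        res = sr.enumerate_dyads([_promoter(consensus36)])
        found = {(m.left_arm, m.spacer_len) for m in res.models}
        assert ("AATTTT", 3) in found
        assert ("AAAATT", 15) in found

    def test_gc_promoters_give_empty_ranking(self):
        promoters = [_promoter("GC" * 100, f"p{i}") for i in range(3)]
        res = sr.enumerate_dyads(promoters)
        assert res.models == []

    def test_empty_promoter_list_is_error(self):
        with pytest.raises(ValueError):
            sr.enumerate_dyads([])

    def test_planted_thermanaerovibrio_spacer_recovered(self):
        spec = sr.SyntheticSpec(n_promoters=20, length=400, gc=0.5, seed=3)
        promoters, _ = sr.plant_dyad(
            sr.gen_background(spec), ("AATATT", 21, "AAAATA"), 1.0, seed=4
        )
        res = sr.enumerate_dyads(promoters)
        top = res.models[0]
        assert top.spacer_len == 21
        assert top.support == 20

    def test_ranking_deterministic_and_total(self, planted_promoters):
        promoters, _ = planted_promoters
        a = sr.enumerate_dyads(promoters).models
        b = sr.enumerate_dyads(promoters).models
        assert [(m.left_arm, m.spacer_len) for m in a] == [
            (m.left_arm, m.spacer_len) for m in b
        ]
        pvals = [m.p_value for m in a]
        assert pvals == sorted(pvals)

    def test_strand_symmetry_of_discovery(self, planted_promoters):
        """Reverse-complementing every promoter leaves dyads invariant."""
        promoters, _ = planted_promoters
        flipped = [
            sr.Promoter(p.locus_id, sr.reverse_complement(p.sequence), p.contig_id, p.interval, p.strand)
            for p in promoters
        ]
        a = {(m.left_arm, m.spacer_len, m.support) for m in sr.enumerate_dyads(promoters).models}
        b = {(m.left_arm, m.spacer_len, m.support) for m in sr.enumerate_dyads(flipped).models}
        assert a == b

    def test_min_motif_span_excludes_short_dyads(self):
        cfg = sr.DyadConfig()
        assert min(cfg.spacer_range()) == 3  # 2*6 + 3 = 15


class TestBackgroundNull:
    def test_uniform_closed_form(self):
        # uniform composition, one promoter exactly the motif span: S = 1
        seq = "ACGT" * 5  # length 20 >= span 18? use spacer 8 -> span 20
        p = _promoter(seq)
        p0 = sr.background_word_prob([p], "AATTTT", 8)
        p_site = (0.25) ** 12
        assert p0 == pytest.approx(2 * p_site - p_site**2, rel=1e-12)

    def test_gc_only_background_zero(self):
        p = _promoter("GC" * 50)
        assert sr.background_word_prob([p], "AATTTT", 5) == 0.0

    def test_fixed_specification_uniform(self):
        # composition exactly uniform; S start positions
        seq = "ACGT" * 100
        p = _promoter(seq)
        spacer = 3
        p0 = sr.background_word_prob([p], "AATTTT", spacer)
        S = 400 - (12 + spacer) + 1
        assert p0 == pytest.approx(1 - (1 - 0.25**12) ** (2 * S), rel=1e-9)

    def test_neighbourhood_prob_equals_enumeration(self):
        bg = {"A": 0.3, "C": 0.2, "G": 0.2, "T": 0.3}
        word = "AATGCT"
        for mm in (0, 1, 2):
            brute = 0.0
            for nb in _mismatch_neighbourhood(word, mm):
                q = 1.0
                for ch in nb:
                    q *= bg[ch]
                brute += q
            assert _neighbourhood_prob(word, bg, mm) == pytest.approx(brute, rel=1e-12)


class TestSignificance:
    def test_zero_support_is_one(self):
        assert sr.score_dyad_significance(0, 10, 0.1) == 1.0

    def test_full_support_closed_form(self):
        assert sr.score_dyad_significance(5, 5, 0.2, m=1) == pytest.approx(0.2**5)

    def test_matches_direct_binomial_sum(self):
        k, n, p0 = 3, 10, 0.1
        expected = sum(
            comb(n, j) * p0**j * (1 - p0) ** (n - j) for j in range(k, n + 1)
        )
        assert sr.score_dyad_significance(k, n, p0, m=1) == pytest.approx(expected)

    def test_bonferroni_clamped(self):
        assert sr.score_dyad_significance(1, 10, 0.5, m=10**6) == 1.0

    def test_invalid_ranges_rejected(self):
        with pytest.raises(ValueError):
            sr.score_dyad_significance(-1, 10, 0.1)
        with pytest.raises(ValueError):
            sr.score_dyad_significance(3, 10, 1.5)
        with pytest.raises(ValueError):
            sr.score_dyad_significance(3, 10, 0.1, m=0)

    def test_background_only_calibration(self):
        """On unplanted promoters few hypotheses reach Bonferroni p < 0.05."""
        n_sets = 50
        sig_fractions = []
        for s in range(n_sets):
            spec = sr.SyntheticSpec(n_promoters=10, length=200, gc=0.5, seed=1000 + s)
            promoters = sr.gen_background(spec)
            cfg = sr.DyadConfig(spacer_max=15)
            res = sr.enumerate_dyads(promoters, cfg)
            n_sig = sum(m.p_value < 0.05 for m in res.models)
            sig_fractions.append(n_sig / res.n_hypotheses)
        assert np.mean(sig_fractions) <= 0.05


class TestRefineEM:
    def test_planted_bases_dominate_after_convergence(self, planted_promoters):
        promoters, _ = planted_promoters
        res = sr.enumerate_dyads(promoters)
        refined = sr.refine_em(promoters, res.models[0])
        for j, ch in enumerate("AAAATT"):
            assert refined.left_matrix["ACGT".index(ch), j] >= 0.9
        for j, ch in enumerate("AATTTT"):
            assert refined.right_matrix["ACGT".index(ch), j] >= 0.9
        assert refined.spacer_len == 15

    def test_objective_never_decreases(self, planted_promoters):
        promoters, _ = planted_promoters
        res = sr.enumerate_dyads(promoters)
        trace = []
        sr.refine_em(promoters, res.models[0], trace=trace)
        assert all(b >= a - 1e-8 for a, b in zip(trace, trace[1:]))

    def test_objective_monotone_on_random_fixtures(self):
        """EM monotonicity holds on background-only inputs as well."""
        for s in range(5):
            spec = sr.SyntheticSpec(n_promoters=6, length=80, gc=0.45, seed=500 + s)
            promoters = sr.gen_background(spec)
            seed_model = sr.DyadModel(
                arm_len=6, left_arm="AATTTT", right_arm="AAAATT",
                spacer_len=5, support=1, n_promoters=len(promoters),
            )
            cfg = sr.DyadConfig(spacer_min=3, spacer_max=8, em_max_iter=40)
            trace = []
            sr.refine_em(promoters, seed_model, cfg, trace=trace)
            assert all(b >= a - 1e-8 for a, b in zip(trace, trace[1:]))

    def test_deterministic(self, planted_promoters):
        promoters, _ = planted_promoters
        res = sr.enumerate_dyads(promoters)
        m1 = sr.refine_em(promoters, res.models[0])
        m2 = sr.refine_em(promoters, res.models[0])
        assert np.array_equal(m1.left_matrix, m2.left_matrix)
        assert m1.spacer_weights == m2.spacer_weights

    def test_column_sums_are_one(self, planted_promoters):
        promoters, _ = planted_promoters
        res = sr.enumerate_dyads(promoters)
        refined = sr.refine_em(promoters, res.models[0])
        assert np.allclose(refined.left_matrix.sum(axis=0), 1.0, atol=1e-9)
        assert np.allclose(refined.right_matrix.sum(axis=0), 1.0, atol=1e-9)
        assert sum(refined.spacer_weights.values()) == pytest.approx(1.0)


class TestConsensus:
    def test_single_base_columns(self):
        model = sr.DyadModel(
            arm_len=2,
            left_arm="AT",
            right_arm="AT",
            spacer_len=3,
            support=1,
            n_promoters=1,
            left_matrix=np.array([[1.0, 0.0], [0, 0], [0, 0], [0.0, 1.0]]),
            right_matrix=np.array([[1.0, 0.0], [0, 0], [0, 0], [0.0, 1.0]]),
        )
        assert sr.consensus_iupac(model) == "ATNNNAT"

    def test_cg_column_maps_to_S(self):
        mat = np.array([[0.0], [0.5], [0.5], [0.0]])
        model = sr.DyadModel(
            arm_len=1, left_arm="C", right_arm="G", spacer_len=0,
            support=1, n_promoters=1, left_matrix=mat, right_matrix=mat,
        )
        assert sr.consensus_iupac(model) == "SS"

    def test_flat_column_maps_to_N(self):
        mat = np.array([[0.28], [0.26], [0.24], [0.22]])
        model = sr.DyadModel(
            arm_len=1, left_arm="A", right_arm="A", spacer_len=0,
            support=1, n_promoters=1, left_matrix=mat, right_matrix=mat,
        )
        assert sr.consensus_iupac(model) == "NN"

    def test_word_fallback_without_matrices(self):
        model = sr.DyadModel(
            arm_len=6, left_arm="AAAATT", right_arm="AATTTT",
            spacer_len=15, support=20, n_promoters=20,
        )
        assert sr.consensus_iupac(model) == "AAAATT" + "N" * 15 + "AATTTT"


class TestSerialisation:
    def test_json_roundtrip(self, planted_promoters, tmp_path):
        promoters, _ = planted_promoters
        res = sr.enumerate_dyads(promoters)
        refined = sr.refine_em(promoters, res.models[0])
        path = tmp_path / "motif.json"
        refined.save_json(path)
        again = sr.DyadModel.load_json(path)
        assert again.left_arm == refined.left_arm
        assert again.spacer_len == refined.spacer_len
        assert np.allclose(again.left_matrix, refined.left_matrix)
        assert again.spacer_weights == refined.spacer_weights

    def test_meme_minimal_export(self, tmp_path):
        model = sr.DyadModel(
            arm_len=6, left_arm="AAAATT", right_arm="AATTTT",
            spacer_len=15, support=20, n_promoters=20,
        )
        path = tmp_path / "motif.meme"
        sr.write_meme_minimal(model, path)
        text = path.read_text()
        assert "MEME version 4" in text
        assert "alength= 4 w= 27" in text
        # 27 matrix rows, each summing to 1
        rows = [l for l in text.splitlines() if l and l[0].isdigit()]
        assert len(rows) == 27
        for row in rows:
            assert math.isclose(sum(float(x) for x in row.split()), 1.0, abs_tol=1e-5)


class TestCandidateWords:
    def test_at_fraction_filter(self):
        words = candidate_arm_words(sr.DyadConfig())
        assert "AATTTT" in words and "ATTTTC" in words
        assert "GGGGGG" not in words and "AATTCC" not in words
        # 2^6 pure-AT words plus 6 positions x 2 non-AT bases x 2^5
        assert len(words) == 64 + 6 * 2 * 32

    def test_hamming_requires_equal_length(self):
        with pytest.raises(ValueError):
            hamming("AA", "AAA")
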