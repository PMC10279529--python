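"""Enrichment statistics against enumeration oracles and planted signals."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tetherscore.config import EnrichmentConfig
from tetherscore.enrichment import (
    AMINO_ACIDS,
    MotifMatrix,
    bh_adjust,
    build_rbp_set,
    compare_rbp_activity,
    composition_entropy,
    domain_enrichment,
    filter_motif_results,
    hypergeom_tail,
    mann_whitney_u,
    parse_meme_motifs,
    ppi_enrichment,
    prepare_motif_input,
    pwm_scan,
    select_active,
)
from tetherscore.errors import InputError


def scores_frame(vals, reads=2000):
    return pd.DataFrame({
        "mu_hat": vals, "score": vals, "total_reads": [reads] * len(vals),
        "n_barcodes": [1] * len(vals), "replicate_id": "rep1",
    }, index=pd.Index([f"f{i}" for i in range(len(vals))], name="fragment_id"))


def fragments_frame(genes, intervals=None):
    n = len(genes)
    intervals = intervals or [(1 + 10 * i, 100 + 10 * i) for i in range(n)]
    return pd.DataFrame({
        "fragment_id": [f"f{i}" for i in range(n)],
        "gene_id": genes,
        "aa_start": [iv[0] for iv in intervals],
        "aa_end": [iv[1] for iv in intervals],
    })


class TestSelectActive:
    def test_sign_labels(self):
        out = select_active(scores_frame([-1.5, 0.0, 1.5]))
        assert list(out["direction"]) == ["repressor", "activator"]

    def test_boundary_value_excluded(self):
        out = select_active(scores_frame([1.0, -1.0, 1.0001]))
        assert list(out.index) == ["f2"]


class TestMannWhitney:
    def test_exact_small_sample_enumeration(self):
        """x={1,2}, y={3,4}: U=0, two-sided exact p = 1/3."""
        U, p = mann_whitney_u([1, 2], [3, 4])
        assert U == 0
        assert p == pytest.approx(1 / 3)

    @pytest.mark.parametrize("x,y", [
        ([1, 5], [2, 8, 9]),
        ([3, 1, 7], [2, 9, 11, 4]),
        ([10, 20, 30, 40], [15, 25]),
    ])
    def test_exact_branch_matches_itertools_enumeration(self, x, y):
        """Exact p equals the tail fraction over all C(n+m, n) labelings."""
        U_obs, p_obs = mann_whitney_u(x, y)
        pooled = sorted(x + y)
        n = len(x)

        def u_of(subset):
            xs = [pooled[i] for i in subset]
            ys = [pooled[i] for i in range(len(pooled)) if i not in subset]
            return sum(1 for a in xs for b in ys if a > b) + \
                0.5 * sum(1 for a in xs for b in ys if a == b)

        us = [u_of(s) for s in itertools.combinations(range(len(pooled)), n)]
        mean_u = len(x) * len(y) / 2
        dev = abs(u_of(tuple(sorted(pooled.index(v) for v in x))) - mean_u)
        # two-sided: arrangements at least as extreme on either side
        p_exact = sum(1 for u in us if abs(u - mean_u) >= dev - 1e-12) / len(us)
        assert p_obs == pytest.approx(p_exact)

    def test_identical_samples_p_near_one(self):
        _, p = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p > 0.95

    def test_empty_sample_raises(self):
        with pytest.raises(InputError):
            mann_whitney_u([], [1.0])

    def test_exact_and_asymptotic_agree_at_branch_point(self):
        # at min(n, m) = 8 the continuity-corrected normal approximation
        # tracks the exact null distribution to ~0.01 in p
        from scipy.stats import mannwhitneyu
        rng = np.random.default_rng(5)
        for _ in range(20):
            x = rng.normal(size=8)
            y = rng.normal(size=9)
            p_ex = mannwhitneyu(x, y, method="exact").pvalue
            p_as = mannwhitneyu(x, y, method="asymptotic",
                                use_continuity=True).pvalue
            assert abs(p_ex - p_as) <= 0.011


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_step_up_formula(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_rejects_out_of_range(self):
        with pytest.raises(InputError):
            bh_adjust([0.5, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_brute_force_step_up(self, ps):
        """q_(i) = min_{j>=i} m p_(j) / j, order preserved."""
        q = bh_adjust(ps)
        m = len(ps)
        order = np.argsort(ps, kind="mergesort")
        expected = np.empty(m)
        for rank_pos, idx in enumerate(order):
            candidates = [min(1.0, m * ps[order[j]] / (j + 1))
                          for j in range(rank_pos, m)]
            expected[idx] = min(candidates)
        np.testing.assert_allclose(q, expected, atol=1e-12)


class TestHypergeom:
    @pytest.mark.parametrize("k,N,K,n", [
        (5, 100, 10, 10), (0, 50, 5, 10), (3, 20, 8, 6), (8, 200, 40, 20),
    ])
    def test_matches_direct_tail_summation(self, k, N, K, n):
        def comb(a, b):
            return math.comb(a, b) if 0 <= b <= a else 0

        p_direct = sum(
            comb(K, j) * comb(N - K, n - j) for j in range(k, min(K, n) + 1)
        ) / comb(N, n)
        assert hypergeom_tail(k, N, K, n) == pytest.approx(p_direct, rel=1e-10)


class TestDomainEnrichment:
    def test_planted_active_family_is_flagged(self):
        """One family's fragments all strongly active -> flagged positive."""
        rng = np.random.default_rng(7)
        n_null = 60
        genes = [f"g{i}" for i in range(n_null)] + ["hot1", "hot2", "hot3"]
        vals = list(rng.normal(0, 0.3, n_null)) + [2.5, 2.6, 2.4]
        scores = scores_frame(vals)
        frags = fragments_frame(genes, intervals=[(1, 100)] * len(genes))
        domains = pd.DataFrame({
            "protein_id": ["hot1", "hot2", "hot3", "g0", "g1"],
            "family_id": ["FAM_HOT"] * 3 + ["FAM_COLD"] * 2,
            "aa_start": [10] * 5, "aa_end": [60] * 5,
        })
        res = domain_enrichment(scores, frags, domains)
        assert list(res["family_id"]) == ["FAM_HOT"]  # cold family not active
        row = res.iloc[0]
        assert row["mean_activity"] > 2
        assert row["significant"]

    def test_insufficient_coverage_excludes_family(self):
        scores = scores_frame([2.5, 0.0, 0.1])
        frags = fragments_frame(["g1", "g2", "g3"],
                                intervals=[(1, 60), (1, 50), (1, 50)])
        # fragment covers 60 of domain 1-100 -> 0.6 < 0.75
        domains = pd.DataFrame({"protein_id": ["g1"], "family_id": ["FAM"],
                                "aa_start": [1], "aa_end": [100]})
        res = domain_enrichment(scores, frags, domains)
        assert res.empty

    def test_overlapping_active_fragments_collapse_to_representative(self):
        scores = scores_frame([2.5, 2.6, 0.0, 0.0], reads=100)
        scores.loc["f1", "total_reads"] = 999  # most highly sequenced
        frags = fragments_frame(["g1", "g1", "g2", "g3"],
                                intervals=[(1, 100), (2, 101), (1, 100), (1, 100)])
        domains = pd.DataFrame({"protein_id": ["g1"], "family_id": ["FAM"],
                                "aa_start": [10], "aa_end": [60]})
        res = domain_enrichment(scores, frags, domains)
        assert res.iloc[0]["n_fragments"] == 1  # the two 99%-overlaps merged

    def test_null_scores_no_family_flagged(self):
        rng = np.random.default_rng(11)
        genes = [f"g{i}" for i in range(80)]
        scores = scores_frame(list(rng.normal(0, 1.0, 80)))
        frags = fragments_frame(genes, intervals=[(1, 100)] * 80)
        domains = pd.DataFrame({
            "protein_id": genes[:40],
            "family_id": [f"FAM{i % 8}" for i in range(40)],
            "aa_start": [10] * 40, "aa_end": [60] * 40,
        })
        res = domain_enrichment(scores, frags, domains)
        assert int(res["significant"].sum()) == 0 if len(res) else True


class TestPPIEnrichment:
    def _fixture(self):
        # universe: 100 fragments, 10 activators; hub interacts with genes
        # carrying 10 fragments of which 5 are activators -> fold 5.0
        genes = [f"g{i}" for i in range(100)]
        vals = [2.0] * 5 + [0.0] * 45 + [2.0] * 5 + [0.0] * 45
        scores = scores_frame(vals)
        frags = fragments_frame(genes, intervals=[(1, 100)] * 100)
        partners = genes[:10]  # f0..f9: 5 activators, 5 nulls
        inter = pd.DataFrame({"interactor_a": ["HUB"] * 10,
                              "interactor_b": partners})
        return scores, frags, inter

    def test_fold_enrichment_arithmetic(self):
        scores, frags, inter = self._fixture()
        res = ppi_enrichment(scores, frags, inter, "activator")
        hub = res.set_index("hub_protein_id").loc["HUB"]
        assert hub["n_interactor_fragments"] == 10
        assert hub["n_active_among"] == 5
        assert hub["fold_enrichment"] == pytest.approx(5.0)
        assert hub["p"] == pytest.approx(hypergeom_tail(5, 100, 10, 10))

    def test_background_rate_gives_fold_one(self):
        genes = [f"g{i}" for i in range(50)]
        vals = ([2.0] + [0.0] * 4) * 10  # every 5th fragment an activator
        scores = scores_frame(vals)
        frags = fragments_frame(genes, intervals=[(1, 100)] * 50)
        inter = pd.DataFrame({"interactor_a": ["HUB"] * 5,
                              "interactor_b": genes[:5]})
        res = ppi_enrichment(scores, frags, inter, "activator")
        hub = res.set_index("hub_protein_id").loc["HUB"]
        assert hub["fold_enrichment"] == pytest.approx(1.0)

    def test_repressor_direction_counts_repressors(self):
        scores = scores_frame([-2.0, -1.5, 0.0, 0.2, 2.0])
        frags = fragments_frame([f"g{i}" for i in range(5)],
                                intervals=[(1, 100)] * 5)
        inter = pd.DataFrame({"interactor_a": ["HUB"] * 2,
                              "interactor_b": ["g0", "g1"]})
        res = ppi_enrichment(scores, frags, inter, "repressor")
        hub = res.set_index("hub_protein_id").loc["HUB"]
        assert hub["n_active_among"] == 2


class TestRBP:
    def test_two_of_four_rule(self):
        tab = pd.DataFrame({
            "protein_id": ["a", "b", "c"],
            "d1": [1, 1, 0], "d2": [1, 0, 0], "d3": [0, 0, 1], "d4": [0, 0, 0],
        })
        assert build_rbp_set(tab) == {"a"}

    def test_planted_rbp_group_has_higher_absolute_scores(self):
        rng = np.random.default_rng(13)
        genes = [f"r{i}" for i in range(40)] + [f"n{i}" for i in range(60)]
        vals = list(rng.normal(0, 2.0, 40)) + list(rng.normal(0, 0.3, 60))
        scores = scores_frame(vals)
        frags = fragments_frame(genes, intervals=[(1, 100)] * 100)
        rbp = {f"r{i}" for i in range(40)}
        res = compare_rbp_activity(scores, frags, rbp)
        assert res["median_abs_score_rbp"] > res["median_abs_score_other"]
        assert res["p"] < 1e-4

    def test_empty_group_raises(self):
        scores = scores_frame([1.0, 2.0])
        frags = fragments_frame(["a", "b"], intervals=[(1, 10)] * 2)
        with pytest.raises(InputError):
            compare_rbp_activity(scores, frags, set())


class TestMotifPipeline:
    def test_overlapping_active_fragments_emit_one_record(self):
        scores = scores_frame([2.0, 2.1, -1.8])
        frags = fragments_frame(["g1", "g1", "g2"],
                                intervals=[(1, 100), (5, 104), (10, 40)])
        proteome = {"g1": "A" * 120, "g2": "W" * 60}
        recs = prepare_motif_input(scores, frags, proteome)
        assert len(recs) == 2  # g1's two 90%-overlaps collapse at 50%
        headers = {h for h, _ in recs}
        assert "g2(10-40)" in headers
        peptide = dict(recs)["g2(10-40)"]
        assert peptide == "W" * 31

    def test_empty_active_set_raises(self):
        scores = scores_frame([0.1, -0.2])
        frags = fragments_frame(["g1", "g2"], intervals=[(1, 50)] * 2)
        with pytest.raises(InputError):
            prepare_motif_input(scores, frags, {"g1": "A" * 60, "g2": "A" * 60})

    def _uniform_pwm(self, L):
        return np.full((L, 20), 1 / 20)

    def _onehot_pwm(self, peptide):
        pwm = np.zeros((len(peptide), 20))
        for i, aa in enumerate(peptide):
            pwm[i, AMINO_ACIDS.index(aa)] = 1.0
        return pwm

    def test_single_source_motif_dropped(self):
        m = MotifMatrix("m1", self._uniform_pwm(4), source_proteins=["only"])
        kept, _ = filter_motif_results([m])
        assert kept == []

    def test_polyq_zero_entropy_dropped(self):
        pwm = self._onehot_pwm("QQQQQQQQ")
        m = MotifMatrix("m1", pwm, source_proteins=["a", "b"])
        assert composition_entropy(m.consensus) == 0.0
        kept, _ = filter_motif_results([m])
        assert kept == []

    def test_mixed_fixture_rule_by_rule(self):
        good = MotifMatrix("good", self._onehot_pwm("KRDEFGHI"),
                           source_proteins=["a", "b", "c"])
        single = MotifMatrix("single", self._onehot_pwm("KRDEFGHI"),
                             source_proteins=["a"])
        lowc = MotifMatrix("lowc", self._onehot_pwm("QNQNQNQN"),
                           source_proteins=["a", "b"])
        aln = pd.DataFrame({
            "motif_id": ["good", "good", "single", "lowc"],
            "protein_id": ["p1", "p2", "p3", "p4"],
            "start": [1, 5, 2, 3],
            "matched_seq": ["KRDEFGHI", "QQQQQQQQ", "KRDEFGHI", "QNQNQNQN"],
        })
        kept, kept_aln = filter_motif_results([good, single, lowc], aln)
        assert [m.motif_id for m in kept] == ["good"]
        # good's second alignment hits a repetitive target window
        assert len(kept_aln) == 1
        assert kept_aln.iloc[0]["protein_id"] == "p1"

    def test_pwm_scan_uniform_background_scores_zero(self):
        m = MotifMatrix("m", self._uniform_pwm(5), source_proteins=["a", "b"])
        hits = pwm_scan("ACDEFGHIKL", m, threshold=-1e-9)
        assert all(abs(s) < 1e-9 for _, s in hits)
        assert len(hits) == 6

    def test_one_hot_log_odds_score(self):
        """One-hot 'KRKR' on a matching window: 4 * log2(20) ~ 17.29."""
        m = MotifMatrix("m", self._onehot_pwm("KRKR"), source_proteins=["a", "b"])
        hits = pwm_scan("AAKRKRAA", m, threshold=1.0)
        assert len(hits) == 1
        pos, score = hits[0]
        assert pos == 3
        assert score == pytest.approx(4 * np.log2(20))

    def test_reversed_match_not_hit(self):
        m = MotifMatrix("m", self._onehot_pwm("KRDE"), source_proteins=["a", "b"])
        assert pwm_scan("AAEDRKAA", m, threshold=1.0) == []

    def test_motif_longer_than_sequence(self):
        m = MotifMatrix("m", self._uniform_pwm(10), source_proteins=["a", "b"])
        assert pwm_scan("ACD", m) == []

    def test_meme_parser_round_trip(self):
        text = (
            "MEME version 4\n\nALPHABET= " + AMINO_ACIDS + "\n\n"
            "MOTIF motif_A\n"
            "letter-probability matrix: alength= 20 w= 3 nsites= 18\n"
            + "\n".join(" ".join(f"{v:.6f}" for v in row)
                        for row in np.full((3, 20), 0.05))
            + "\n"
        )
        motifs = parse_meme_motifs(text)
        assert len(motifs) == 1
        assert motifs[0].motif_id == "motif_A"
        assert motifs[0].pwm.shape == (3, 20)
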