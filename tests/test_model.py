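"""All-pairs screening model, concordance summary and prevalence grids."""

import numpy as np
import pandas as pd
import pytest

from cooc import (
    AnalysisConfig,
    CountTable,
    HypergeomNullParams,
    PairwiseCooccurrence,
    PresenceAbsenceMatrix,
    analyze_all_pairs,
    concordance_summary,
    hypergeometric_null,
    n_unique_pairs,
    prevalence_grid,
    rare_pair_fractions,
    tail_probabilities,
)


def _pa(rows, prefix="t"):
    arr = np.array(rows)
    return PresenceAbsenceMatrix(
        [f"{prefix}{i}" for i in range(arr.shape[0])],
        [f"s{j}" for j in range(arr.shape[1])],
        arr,
    )


class TestPairCount:
    @pytest.mark.parametrize("n, expected", [(1300, 844350), (2, 1), (10, 45)])
    def test_closed_form(self, n, expected):
        assert n_unique_pairs(n) == expected

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            n_unique_pairs(1)

    def test_bonferroni_alpha_times_pairs_is_family_alpha(self):
        rng = np.random.default_rng(0)
        pa = _pa(rng.integers(0, 2, size=(8, 20)))
        model = PairwiseCooccurrence(pa)
        assert model.alpha_per_test * model.n_pairs == pytest.approx(0.05)


class TestAnalyzeAllPairs:
    def test_identical_rows_positive_in_both_metrics(self):
        row = [1] * 20 + [0] * 20
        pairs = analyze_all_pairs(_pa([row, row]))
        rec = pairs.iloc[0]
        assert rec["dir_J"] == "positive" and rec["dir_r"] == "positive"
        assert rec["sig_J"] and rec["sig_r"]

    def test_independent_taxa_rarely_significant(self):
        """Under familywise control, 50 independent taxa should yield no calls."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            prev = rng.uniform(0.1, 0.9, size=50)
            occ = (rng.random((50, 120)) < prev[:, None]).astype(np.uint8)
            pairs = analyze_all_pairs(_pa(occ))
            if pairs["sig_J"].any() or pairs["sig_r"].any():
                hits += 1
        assert hits <= 1  # at most 1 of 10 seeds shows any familywise error

    def test_engineered_pair_detected_among_decoys(self):
        """A strongly co-occurring pair (a=40,b=2,c=2,d=56) must be flagged
        significant-positive for J, and its tail p must match the null module."""
        rng = np.random.default_rng(123)
        N = 100
        x1 = np.array([1] * 42 + [0] * 58)
        x2 = np.array([1] * 40 + [0] * 2 + [1] * 2 + [0] * 56)
        decoys = (rng.random((8, N)) < 0.3).astype(np.uint8)
        pa = _pa(np.vstack([x1, x2, decoys]))
        results = PairwiseCooccurrence(pa).fit()
        rec = results.pairs[
            (results.pairs["taxon_i"] == "t0") & (results.pairs["taxon_j"] == "t1")
        ].iloc[0]
        assert (rec["a"], rec["b"], rec["c"], rec["d"]) == (40, 2, 2, 56)
        dist = hypergeometric_null(HypergeomNullParams(m=42, n_unocc=58, k=42))
        oracle_p = tail_probabilities(dist, 40).p_ge
        assert rec["p_J_ge_hyper"] == pytest.approx(oracle_p, rel=1e-10)
        assert oracle_p < results.alpha_per_test
        assert rec["sig_J"] and rec["dir_J"] == "positive"

    def test_degenerate_taxa_flagged_never_significant(self):
        pa = _pa([[1, 1, 0, 0], [0, 0, 0, 0], [1, 1, 1, 1]])
        pairs = analyze_all_pairs(pa)
        degen = pairs[pairs["degenerate"]]
        assert len(degen) == 3  # every pair touches an all-0 or all-1 taxon
        assert not degen["sig_J"].any() and not degen["sig_r"].any()

    def test_determinism(self):
        rng = np.random.default_rng(5)
        pa = _pa(rng.integers(0, 2, size=(12, 30)))
        t1 = analyze_all_pairs(pa)
        t2 = analyze_all_pairs(pa)
        pd.testing.assert_frame_equal(t1, t2)

    def test_from_counts_applies_threshold(self):
        counts = CountTable(
            ["a", "b"], ["s1", "s2", "s3"], np.array([[150, 0, 99], [101, 101, 0]])
        )
        model = PairwiseCooccurrence.from_counts(counts, min_reads=100)
        np.testing.assert_array_equal(model.pa.occupancy, [[1, 0, 0], [1, 1, 0]])

    def test_pair_p_values_match_per_pair_nulls(self):
        """Vectorized engine tails equal the per-pair null-module computation."""
        rng = np.random.default_rng(9)
        pa = _pa(rng.integers(0, 2, size=(6, 25)))
        pairs = analyze_all_pairs(pa)
        from cooc import contingency_for_pair

        idx = {t: k for k, t in enumerate(pa.taxon_ids)}
        for _, rec in pairs.iterrows():
            i, j = idx[rec["taxon_i"]], idx[rec["taxon_j"]]
            t = contingency_for_pair(pa, i, j)
            dist = hypergeometric_null(
                HypergeomNullParams(m=t.a + t.b, n_unocc=t.c + t.d, k=t.a + t.c)
            )
            tails = tail_probabilities(dist, t.a)
            assert rec["p_J_ge_hyper"] == pytest.approx(tails.p_ge, rel=1e-10)
            assert rec["p_J_le_hyper"] == pytest.approx(tails.p_le, rel=1e-10)


class TestConcordance:
    def _pairs_frame(self, sig_j, sig_r, dir_j=None, dir_r=None):
        n = len(sig_j)
        return pd.DataFrame(
            {
                "sig_J": sig_j,
                "sig_r": sig_r,
                "dir_J": dir_j or ["positive"] * n,
                "dir_r": dir_r or ["positive"] * n,
            }
        )

    def test_all_significant_same_direction(self):
        pairs = self._pairs_frame([True] * 4, [True] * 4)
        s = concordance_summary(pairs)
        assert s.frac_both_of_union == 1.0
        assert s.direction_match_count == 4

    def test_partial_overlap_fractions(self):
        # sig_r = {p1, p2}, sig_J = {p2, p3}
        pairs = self._pairs_frame([False, True, True], [True, True, False])
        s = concordance_summary(pairs)
        assert s.frac_r_only_of_sig_r == pytest.approx(0.5)
        assert s.frac_J_only_of_sig_J == pytest.approx(0.5)
        assert s.frac_both_of_union == pytest.approx(1 / 3)

    def test_no_significant_pairs_undefined_fractions(self):
        s = concordance_summary(self._pairs_frame([False] * 3, [False] * 3))
        assert s.frac_r_only_of_sig_r is None
        assert s.frac_J_only_of_sig_J is None
        assert s.frac_both_of_union is None
        assert s.n_sig_both == 0

    def test_direction_mismatch_counted_not_assumed(self):
        pairs = self._pairs_frame(
            [True, True], [True, True],
            dir_j=["positive", "negative"], dir_r=["positive", "positive"],
        )
        assert concordance_summary(pairs).direction_match_count == 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            concordance_summary(pd.DataFrame(columns=["sig_J", "sig_r"]))


class TestPrevalenceGrid:
    def _single_pair_frame(self, p_i, p_j, sig_j=False, sig_r=False):
        return pd.DataFrame(
            {
                "prevalence_i": [p_i], "prevalence_j": [p_j],
                "sig_J": [sig_j], "sig_r": [sig_r],
            }
        )

    def test_binning_by_sorted_prevalences(self):
        grid = prevalence_grid(self._single_pair_frame(0.07, 0.03))
        assert grid.total[0, 1] == 1  # row = [0,0.05), col = [0.05,0.10)
        assert grid.total.sum() == 1

    def test_prevalence_one_falls_in_last_closed_bin(self):
        grid = prevalence_grid(self._single_pair_frame(1.0, 1.0))
        assert grid.total[-1, -1] == 1

    def test_grid_conserves_pair_count(self):
        rng = np.random.default_rng(21)
        pa = _pa(rng.integers(0, 2, size=(15, 40)))
        pairs = analyze_all_pairs(pa)
        grid = prevalence_grid(pairs)
        assert grid.total.sum() == len(pairs) == n_unique_pairs(15)
        assert np.all(grid.difference == grid.sig_J.astype(int) - grid.sig_r)

    def test_grid_is_upper_triangular(self):
        rng = np.random.default_rng(2)
        pa = _pa(rng.integers(0, 2, size=(10, 30)))
        grid = prevalence_grid(analyze_all_pairs(pa))
        assert np.all(np.tril(grid.total, k=-1) == 0)


class TestRarePairFractions:
    def test_no_rare_taxa(self):
        pa = _pa([[1, 1, 0, 0]] * 3, prefix="x")
        assert rare_pair_fractions(pa) == (0.0, 0.0)

    def test_two_rare_one_common(self):
        # prevalences 0.05, 0.05, 0.5 over 20 sites
        rare = [1] + [0] * 19
        common = [1] * 10 + [0] * 10
        pa = _pa([rare, rare, common])
        at_least_one, both = rare_pair_fractions(pa)
        assert at_least_one == pytest.approx(1.0)
        assert both == pytest.approx(1 / 3)

    def test_cutoff_is_strict(self):
        # prevalence exactly at the cutoff is NOT rare
        pa = _pa([[1, 0] * 5, [1] * 10], prefix="y")
        cfg = AnalysisConfig(rare_cutoff=0.5, common_cutoff=0.6)
        assert rare_pair_fractions(pa, cfg) == (0.0, 0.0)


class TestResultsSurface:
    def test_summary_mentions_key_quantities(self):
        rng = np.random.default_rng(3)
        pa = _pa(rng.integers(0, 2, size=(10, 30)))
        res = PairwiseCooccurrence(pa).fit()
        text = res.summary()
        assert "unordered pairs:     45" in text
        assert "familywise alpha" in text

    def test_edge_list_contains_only_significant_pairs(self):
        row = [1] * 15 + [0] * 15
        res = PairwiseCooccurrence(_pa([row, row, [0, 1] * 15])).fit()
        edges = res.significant_edges("J")
        assert set(edges["dir_J"]) <= {"positive", "negative"}
        assert len(edges) == int(res.pairs["sig_J"].sum())

    def test_round_trip_pair_table(self, tmp_path):
        rng = np.random.default_rng(8)
        pa = _pa(rng.integers(0, 2, size=(6, 20)))
        res = PairwiseCooccurrence(pa).fit()
        path = tmp_path / "pairs.tsv"
        res.to_csv(str(path))
        back = pd.read_csv(path, sep="\t")
        assert list(back.columns) == list(res.pairs.columns)
        assert len(back) == res.n_pairs
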