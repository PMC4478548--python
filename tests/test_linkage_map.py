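import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import kendalltau

from polymap import linkage_map as lm
from polymap import synthetic_data as sd


class TestKosambi:
    def test_zero(self):
        assert lm.kosambi(0.0) == 0.0

    def test_closed_form_at_r_010(self):
        # 25 * ln(1.2 / 0.8) = 10.137 cM
        assert lm.kosambi(0.10) == pytest.approx(25 * math.log(1.2 / 0.8), abs=1e-12)
        assert round(lm.kosambi(0.10), 3) == 10.137

    def test_round_trip(self):
        for r in (0.0, 0.05, 0.25, 0.49):
            assert lm.kosambi_inverse(lm.kosambi(r)) == pytest.approx(r, abs=1e-10)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            lm.kosambi(0.5)
        with pytest.raises(ValueError):
            lm.kosambi(-0.01)
        with pytest.raises(ValueError):
            lm.kosambi_inverse(-1.0)

    def test_strictly_increasing_and_convex(self):
        rs = np.linspace(0, 0.49, 200)
        d = lm.kosambi(rs)
        assert (np.diff(d) > 0).all()
        assert (np.diff(d, 2) > -1e-9).all()


class TestToABH:
    def progeny(self, calls):
        return pd.DataFrame([calls], index=["m1"], columns=[f"i{k}" for k in range(len(calls))])

    def test_recoding_relative_to_parent_a(self):
        parents_a = pd.Series({"m1": "AA"})
        parents_b = pd.Series({"m1": "BB"})
        abh, ledger = lm.to_abh(parents_a, parents_b, self.progeny(["AA", "AB", "BB", "NC"]))
        assert list(abh.loc["m1"]) == ["A", "H", "B", "-"]
        assert ledger.iloc[0]["fate"] == "retained"

    def test_swapped_parents_swap_codes(self):
        abh, _ = lm.to_abh(
            pd.Series({"m1": "BB"}), pd.Series({"m1": "AA"}), self.progeny(["AA", "BB"])
        )
        assert list(abh.loc["m1"]) == ["B", "A"]

    @pytest.mark.parametrize(
        "pa,pb,reason",
        [
            ("AB", "BB", "parent_het"),
            ("AA", "AA", "parents_identical"),
            ("NC", "BB", "parent_nc"),
        ],
    )
    def test_rejection_reasons(self, pa, pb, reason):
        abh, ledger = lm.to_abh(
            pd.Series({"m1": pa}), pd.Series({"m1": pb}), self.progeny(["AA"])
        )
        assert len(abh) == 0
        assert ledger.iloc[0]["fate"] == reason


class TestEstimateRF:
    def test_perfect_cosegregation(self):
        col = np.array(list("AHBHA" * 19))[:93]
        link = lm.estimate_rf(col, col, min_joint=20)
        assert link.rf == pytest.approx(0.0, abs=1e-6)
        assert link.lod > 3

    def test_independent_markers_rhat_half_lod_zero(self):
        rfs, lods = [], []
        for seed in range(10):
            tmap = sd.synthetic_map(2, 1, 0.0)
            abh, _ = sd.simulate_f2(tmap, 500, seed=100 + seed)
            link = lm.estimate_rf(abh.iloc[0], abh.iloc[1])
            rfs.append(link.rf)
            lods.append(link.lod)
        assert np.mean(rfs) == pytest.approx(0.5, abs=3 * 0.02)
        assert np.mean(lods) < 0.5

    def test_parameter_recovery_r_010(self):
        tmap = sd.synthetic_map(1, 2, lm.kosambi(0.10))
        ests = [
            lm.estimate_rf(*sd.simulate_f2(tmap, 1000, seed=s)[0].to_numpy())
            for s in range(20)
        ]
        assert np.mean([e.rf for e in ests]) == pytest.approx(0.10, abs=0.01)

    def test_insufficient_joint_calls_undefined(self):
        a = np.array(["A"] * 10 + ["-"] * 10)
        b = np.array(["-"] * 10 + ["A"] * 10)
        link = lm.estimate_rf(a, b, min_joint=20)
        assert math.isnan(link.rf)

    def test_pairwise_matches_scalar_oracle(self):
        """Vectorised all-pairs EM equals the per-pair estimator."""
        tmap = sd.synthetic_map(1, 4, 40.0)
        abh, _ = sd.simulate_f2(tmap, 200, seed=11, missing_rate=0.05)
        table = lm.pairwise_rf(abh)
        for i, j in itertools.combinations(range(4), 2):
            single = lm.estimate_rf(abh.iloc[i], abh.iloc[j])
            assert table.rf[i, j] == pytest.approx(single.rf, abs=1e-6)
            assert table.lod[i, j] == pytest.approx(single.lod, abs=1e-4)
            assert table.pvalue[i, j] == pytest.approx(single.pvalue, abs=1e-6)

    def test_symmetry(self):
        tmap = sd.synthetic_map(1, 3, 30.0)
        abh, _ = sd.simulate_f2(tmap, 150, seed=12)
        table = lm.pairwise_rf(abh)
        assert np.allclose(table.rf, table.rf.T, equal_nan=True)


class TestGrouping:
    def test_two_chromosomes_recovered(self):
        tmap = sd.synthetic_map(2, 8, 60.0)
        abh, _ = sd.simulate_f2(tmap, 150, seed=2)
        groups = lm.group_markers(lm.pairwise_rf(abh))
        assert len(groups) == 2
        truth_groups = [set(tmap.marker_order(n)) for n in tmap.groups]
        assert {frozenset(g) for g in groups} == {frozenset(t) for t in truth_groups}

    def test_transitive_chain_forms_one_group(self):
        markers = ["a", "b", "c"]
        rf = np.full((3, 3), 0.5)
        lod = np.zeros((3, 3))
        pval = np.ones((3, 3))
        for i, j in ((0, 1), (1, 2)):  # only adjacent pairs linked
            rf[i, j] = rf[j, i] = 0.05
            lod[i, j] = lod[j, i] = 20.0
            pval[i, j] = pval[j, i] = 1e-20
        table = lm.PairwiseTable(markers, rf, lod, pval, np.full((3, 3), 100))
        groups = lm.group_markers(table)
        assert groups == [["a", "b", "c"]]

    def test_all_unlinked_singletons(self):
        markers = list("abcd")
        n = len(markers)
        table = lm.PairwiseTable(
            markers, np.full((n, n), 0.5), np.zeros((n, n)), np.ones((n, n)),
            np.full((n, n), 100),
        )
        groups = lm.group_markers(table)
        assert sorted(len(g) for g in groups) == [1, 1, 1, 1]


class TestOrdering:
    def table_from_rf(self, markers, rf):
        n = len(markers)
        return lm.PairwiseTable(
            markers, rf, np.full((n, n), 10.0), np.zeros((n, n)), np.full((n, n), 100)
        )

    def test_three_bins_ordered_by_exhaustive_oracle(self):
        rf = np.array([[0, 0.05, 0.10], [0.05, 0, 0.05], [0.10, 0.05, 0]])
        order = lm.exhaustive_order(rf)
        assert order in ([0, 1, 2], [2, 1, 0])

    def test_two_markers_either_order(self):
        tmap = sd.synthetic_map(1, 2, 10.0)
        abh, _ = sd.simulate_f2(tmap, 100, seed=3)
        ordered = lm.order_group(abh, list(abh.index))
        assert set(ordered) == set(abh.index)

    def test_heuristic_matches_exhaustive_for_small_groups(self, rng):
        """SARF optimality of the greedy + 2-opt path on <= 6 bins."""
        for trial in range(30):
            n = int(rng.integers(3, 7))
            pts = np.sort(rng.uniform(0, 0.5, n))
            rf = np.abs(pts[:, None] - pts[None, :]) + rng.normal(0, 0.01, (n, n))
            rf = np.clip((rf + rf.T) / 2, 0, 0.5)
            np.fill_diagonal(rf, 0)
            best = lm.sarf(lm.exhaustive_order(rf), rf)
            heur = lm.sarf(lm._two_opt(lm._greedy_seriation(rf), rf), rf)
            assert heur == pytest.approx(best, abs=1e-12)

    def test_identical_columns_collapse_to_one_bin(self):
        matrix = pd.DataFrame(
            [["A", "H", "B"], ["A", "H", "B"], ["B", "H", "A"]],
            index=["m1", "m2", "m3"],
            columns=["i1", "i2", "i3"],
        )
        bins = lm._collapse_bins(matrix, ["m1", "m2", "m3"])
        assert sorted(map(len, bins)) == [1, 2]

    def test_simulated_20_marker_group_order_recovery(self):
        tmap = sd.synthetic_map(1, 20, 100.0)
        abh, _ = sd.simulate_f2(tmap, 500, seed=5)
        ordered = lm.order_group(abh, list(abh.index))
        truth = {m: i for i, m in enumerate(tmap.marker_order("LG01"))}
        ranks = [truth[m] for m in ordered]
        tau = abs(kendalltau(ranks, range(len(ranks))).statistic)
        assert tau >= 0.95


class TestCleanMarkers:
    def make_noisy_group(self, seed=6):
        tmap = sd.synthetic_map(1, 12, 60.0)
        abh, _ = sd.simulate_f2(tmap, 150, seed=seed)
        order = list(abh.index)
        # corrupt one interior marker into pure noise
        noisy = order[5]
        rng = np.random.default_rng(99)
        abh.loc[noisy] = rng.choice(["A", "H", "B"], size=abh.shape[1])
        return abh, order, noisy

    def test_noisy_marker_removed_and_length_shrinks(self):
        abh, order, noisy = self.make_noisy_group()
        before = lm._group_length(abh, order)
        kept, removed = lm.clean_markers(abh, order)
        assert noisy in removed
        assert lm._group_length(abh, kept) < before

    def test_clean_group_is_fixed_point(self):
        # dense spacing (~2 cM) so genuine double crossovers stay rare
        tmap = sd.synthetic_map(1, 10, 20.0)
        abh, _ = sd.simulate_f2(tmap, 200, seed=7)
        kept, removed = lm.clean_markers(abh, list(abh.index))
        assert removed == []

    def test_idempotent_after_convergence(self):
        abh, order, _ = self.make_noisy_group()
        kept, _ = lm.clean_markers(abh, order)
        kept2, removed2 = lm.clean_markers(abh, kept)
        assert kept2 == kept and removed2 == []


class TestFrameworkReorder:
    def test_already_in_framework_order_unchanged(self):
        tmap = sd.synthetic_map(1, 8, 40.0)
        abh, _ = sd.simulate_f2(tmap, 200, seed=8)
        order = lm.order_group(abh, list(abh.index))
        result = lm.framework_reorder(abh, order, order)
        assert result == order

    def test_central_inversion_corrected(self):
        """A framework fixes an artificial inversion and shortens the map."""
        tmap = sd.synthetic_map(1, 12, 70.0)
        abh, _ = sd.simulate_f2(tmap, 200, seed=9)
        truth = list(tmap.marker_order("LG01"))
        inverted = truth[:3] + truth[3:9][::-1] + truth[9:]
        before = lm._group_length(abh, inverted)
        result = lm.framework_reorder(abh, inverted, truth)
        after = lm._group_length(abh, result)
        assert result in (truth, truth[::-1])
        assert after < before

    def test_disjoint_framework_rejected(self):
        tmap = sd.synthetic_map(1, 4, 20.0)
        abh, _ = sd.simulate_f2(tmap, 100, seed=10)
        with pytest.raises(ValueError, match="fewer than 2"):
            lm.framework_reorder(abh, list(abh.index), ["x", "y"])


class TestCrossovers:
    def profile_for(self, columns):
        markers = [f"m{i}" for i in range(len(columns[0]))]
        matrix = pd.DataFrame(
            np.array(columns, dtype=object).T,
            index=markers,
            columns=[f"i{k}" for k in range(len(columns))],
        )
        gmap = lm.GeneticMap(
            groups={"LG01": pd.DataFrame({"marker": markers, "cm": np.arange(len(markers), dtype=float)})}
        )
        return lm.count_crossovers(matrix, gmap)

    def test_hand_enumerated_transitions(self):
        prof = self.profile_for([list("AAHHB")])
        assert prof.per_individual.iloc[0, 0] == 2

    def test_constant_column_zero(self):
        prof = self.profile_for([list("BBBBB")])
        assert prof.per_individual.iloc[0, 0] == 0

    def test_missing_skipped_a_to_b_counts_two(self):
        prof = self.profile_for([list("A-B")])
        assert prof.per_individual.iloc[0, 0] == 2

    def test_outlier_flagging(self):
        normal = list("AAAAAAAAAB")  # 1 crossover
        wild = list("ABABABABAB")  # 18 crossover-equivalents
        prof = self.profile_for([normal] * 9 + [wild])
        assert prof.outliers.iloc[9, 0]
        assert not prof.outliers.iloc[0, 0]

    def test_totals_sum_over_groups(self):
        tmap = sd.synthetic_map(3, 5, 40.0)
        abh, _ = sd.simulate_f2(tmap, 60, seed=13)
        prof = lm.count_crossovers(abh, tmap)
        assert (prof.totals == prof.per_individual.sum(axis=1)).all()


class TestRecombinationBins:
    def bins_for(self, rows):
        markers = [f"m{i}" for i in range(len(rows))]
        matrix = pd.DataFrame(rows, index=markers, columns=[f"i{k}" for k in range(len(rows[0]))])
        gmap = lm.GeneticMap(
            groups={"G": pd.DataFrame({"marker": markers, "cm": np.arange(len(markers), dtype=float)})}
        )
        return lm.recombination_bins(matrix, gmap)

    def test_three_bins_from_xxyyz(self):
        x, y, z = list("AHB"), list("AAB"), list("BBB")
        out = self.bins_for([x, x, y, y, z])
        assert out.iloc[0]["n_bins"] == 3
        assert out.iloc[0]["markers_per_bin"] == pytest.approx(5 / 3)

    def test_identical_columns_one_bin(self):
        out = self.bins_for([list("AHB")] * 4)
        assert out.iloc[0]["n_bins"] == 1

    def test_all_distinct_bins_equal_markers(self):
        out = self.bins_for([list("AAA"), list("HHH"), list("BBB")])
        assert out.iloc[0]["n_bins"] == 3

    def test_missing_is_wildcard(self):
        out = self.bins_for([list("AHB"), list("A-B"), list("AHB")])
        assert out.iloc[0]["n_bins"] == 1


class TestSegregationDistortion:
    def matrix_from_counts(self, na, nh, nb):
        return pd.DataFrame(
            [["A"] * na + ["H"] * nh + ["B"] * nb],
            index=["m1"],
            columns=[f"i{k}" for k in range(na + nh + nb)],
        )

    def test_perfect_ratio_zero_statistic(self):
        res = lm.segregation_distortion(self.matrix_from_counts(25, 50, 25))
        assert res.iloc[0]["chi2"] == 0.0
        assert not res.iloc[0]["distorted"]

    def test_hand_arithmetic_oracle(self):
        # counts (40, 40, 13), expected (23.25, 46.5, 23.25):
        # chi2 = 16.75^2/23.25 + 6.5^2/46.5 + 10.25^2/23.25 = 17.4946
        res = lm.segregation_distortion(self.matrix_from_counts(40, 40, 13))
        expect = 16.75**2 / 23.25 + 6.5**2 / 46.5 + 10.25**2 / 23.25
        assert res.iloc[0]["chi2"] == pytest.approx(expect, abs=1e-9)
        assert res.iloc[0]["distorted"]
        assert res.iloc[0]["het_deficit"]
        assert res.iloc[0]["favored_parent"] == "A"

    def test_summary_fractions(self):
        rows = [["A"] * 60 + ["H"] * 30 + ["B"] * 10,  # distorted, favors A
                ["A"] * 25 + ["H"] * 50 + ["B"] * 25]  # mendelian
        matrix = pd.DataFrame(rows, index=["m1", "m2"],
                              columns=[f"i{k}" for k in range(100)])
        res = lm.segregation_distortion(matrix)
        summary = res.attrs["summary"]
        assert summary["n_distorted"] == 1
        assert summary["distorted_fraction"] == 0.5
        assert summary["female_to_male_favored_ratio"] == math.inf

    def test_all_missing_marker_excluded_with_warning(self):
        matrix = pd.DataFrame(
            [["-"] * 8, ["A"] * 2 + ["H"] * 4 + ["B"] * 2],
            index=["m1", "m2"],
            columns=[f"i{k}" for k in range(8)],
        )
        with pytest.warns(UserWarning, match="m1"):
            res = lm.segregation_distortion(matrix)
        assert list(res["marker"]) == ["m2"]


@settings(max_examples=20, deadline=None, derandomize=True)
@given(r=st.floats(min_value=0.0, max_value=0.49))
def test_kosambi_round_trip_property(r):
    assert lm.kosambi_inverse(lm.kosambi(r)) == pytest.approx(r, abs=1e-10)
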