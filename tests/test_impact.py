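"""Permutation tests, effect sizes, and the Composite Sensitivity Index."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from carescreen.impact import (
    cohens_d,
    csi_compute,
    csi_z,
    d_label,
    fisher_q_compare,
    min_detectable_d,
    permutation_nested_mean_test,
    q_label,
    rank_agreement,
    top_k_report,
)

# the published worked table: item -> (factor, |dM|, |dr|, |dlam|, CSI, type)
TABLE7 = {
    "SDAS_27": ("environment", 0.053, 0.371, 0.379, 0.803, "standard"),
    "SDAS_03": ("economy", 0.052, 0.259, 0.294, 0.605, "standard"),
    "SDAS_04": ("economy", 0.047, 0.253, 0.304, 0.604, "standard"),
    "SDAS_25": ("environment", 0.071, 0.150, 0.152, 0.373, "standard"),
    "SDAS_35": ("environment", 0.150, 0.049, 0.084, 0.283, "reverse"),
    "SDAS_31": ("environment", 0.146, 0.023, 0.055, 0.224, "reverse"),
    "SDAS_08": ("economy", 0.110, 0.035, 0.058, 0.203, "reverse"),
    "SDAS_24": ("environment", 0.131, 0.008, 0.030, 0.169, "reverse"),
    "SDAS_01": ("economy", 0.087, 0.022, 0.049, 0.158, "reverse"),
    "SDAS_10": ("economy", 0.083, 0.019, 0.053, 0.155, "reverse"),
}


def table7_item_stats():
    """Two item-stat frames whose differences equal the printed components."""
    idx = list(TABLE7)
    zero = pd.DataFrame(
        {"M": 0.0, "r_it": 0.0, "loading": 0.0}, index=idx
    )
    diff = pd.DataFrame(
        {
            "M": [TABLE7[i][1] for i in idx],
            "r_it": [TABLE7[i][2] for i in idx],
            "loading": [TABLE7[i][3] for i in idx],
        },
        index=idx,
    )
    return zero, diff


class TestPermutation:
    def test_constant_scores_give_p_one(self):
        res = permutation_nested_mean_test(
            np.full(8, 5.0), np.array([1, 0, 0, 0, 0, 0, 0, 0], bool)
        )
        assert res.observed_delta == 0.0
        assert res.p_two_sided == 1.0
        assert res.exhaustive

    def test_exhaustive_enumeration_hand_example(self):
        # scores (1,2,3,10), flagged = the 10: delta = 4 - 2 = 2 and only
        # one of the four reassignments reaches |2|
        res = permutation_nested_mean_test(
            np.array([1.0, 2.0, 3.0, 10.0]),
            np.array([False, False, False, True]),
        )
        assert res.exhaustive and res.iterations == 4
        assert res.observed_delta == pytest.approx(2.0)
        assert res.p_two_sided == pytest.approx(0.25)

    def test_sampled_agrees_with_exhaustive(self):
        rng = np.random.default_rng(8)
        scores = rng.normal(size=12)
        flags = np.zeros(12, bool)
        flags[:3] = True
        exact = permutation_nested_mean_test(scores, flags)
        assert exact.exhaustive and exact.iterations == math.comb(12, 3)
        sampled = permutation_nested_mean_test(
            scores, flags, B=20_000, seed=1, exhaustive_cap=1
        )
        p = exact.p_two_sided
        band = 2 * math.sqrt(p * (1 - p) / 20_000)
        assert abs(sampled.p_two_sided - p) <= max(band, 0.01)

    def test_all_or_none_flagged_rejected(self):
        with pytest.raises(ValueError):
            permutation_nested_mean_test(np.arange(4.0), np.zeros(4, bool))
        with pytest.raises(ValueError):
            permutation_nested_mean_test(np.arange(4.0), np.ones(4, bool))


class TestCorrelationComparison:
    def test_equal_correlations(self):
        res = fisher_q_compare(0.4, 100, 0.4, 100)
        assert res.fisher_z == 0.0
        assert res.p == pytest.approx(1.0)
        assert res.cohens_q == 0.0

    def test_published_q_value(self):
        res = fisher_q_compare(0.288, 1112, 0.321, 986)
        assert round(res.cohens_q, 3) == 0.036
        assert res.q_label == "negligible"

    def test_q_matches_atanh_definition_on_grid(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            r1, r2 = rng.uniform(-0.9, 0.9, size=2)
            n1, n2 = rng.integers(10, 500, size=2)
            res = fisher_q_compare(r1, int(n1), r2, int(n2))
            assert res.cohens_q == pytest.approx(
                abs(math.atanh(r1) - math.atanh(r2))
            )

    @pytest.mark.parametrize(
        "q, label",
        [(0.05, "negligible"), (0.10, "negligible"), (0.2, "small"),
         (0.30, "small"), (0.4, "medium"), (0.50, "medium"), (0.6, "large")],
    )
    def test_q_bins_with_boundaries(self, q, label):
        assert q_label(q) == label


class TestCohensD:
    def test_identical_groups(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = cohens_d(x, x)
        assert res.cohens_d == 0.0
        assert res.ci[0] < 0 < res.ci[1]

    def test_consistency_under_known_shift(self):
        rng = np.random.default_rng(12)
        a = rng.normal(0.5, 1.0, size=10_000)
        b = rng.normal(0.0, 1.0, size=10_000)
        res = cohens_d(a, b)
        assert res.cohens_d == pytest.approx(0.5, abs=0.03)
        assert res.ci[0] < res.cohens_d < res.ci[1]

    @pytest.mark.parametrize(
        "d, label",
        [(0.15, "negligible"), (0.20, "negligible"), (-0.35, "small"),
         (0.50, "small"), (0.6, "medium"), (0.80, "medium"), (1.2, "large")],
    )
    def test_d_bins_with_boundaries(self, d, label):
        assert d_label(d) == label


class TestMinDetectableD:
    def test_published_sensitivity_value(self):
        assert round(min_detectable_d(986, 126), 2) == 0.27

    def test_balanced_groups_benchmark(self):
        assert min_detectable_d(64, 64) == pytest.approx(0.50, abs=0.005)

    def test_monotone_in_sample_size(self):
        ds = [min_detectable_d(n, n) for n in (50, 200, 1000, 5000)]
        assert all(a > b for a, b in zip(ds, ds[1:]))


class TestCsi:
    def test_published_component_sums(self):
        zero, diff = table7_item_stats()
        table = csi_compute(zero, diff)
        for item, (_, dm, dr, dl, csi, _) in TABLE7.items():
            assert table.at[item, "CSI"] == pytest.approx(csi, abs=5e-4)

    def test_zero_components_zero_csi(self):
        zero, _ = table7_item_stats()
        table = csi_compute(zero, zero)
        assert (table["CSI"] == 0).all()

    def test_symmetric_in_sample_order(self):
        zero, diff = table7_item_stats()
        a = csi_compute(zero, diff)
        b = csi_compute(diff, zero)
        pd.testing.assert_frame_equal(a, b)

    def test_ranks_are_a_permutation(self):
        zero, diff = table7_item_stats()
        table = csi_compute(zero, diff)
        assert sorted(table["rank"]) == list(range(1, len(table) + 1))

    def test_item_set_mismatch_rejected(self):
        zero, diff = table7_item_stats()
        with pytest.raises(ValueError, match="item sets differ"):
            csi_compute(zero, diff.iloc[:-1])


class TestCsiZ:
    def test_identity_when_components_standardized(self):
        rng = np.random.default_rng(11)
        comp = rng.normal(size=(12, 3))
        comp = (comp - comp.mean(0)) / comp.std(0, ddof=1)
        comp = np.abs(comp)  # keep the component semantics
        comp = (comp - comp.mean(0)) / comp.std(0, ddof=1)
        stats_a = pd.DataFrame(
            {"M": 0.0, "r_it": 0.0, "loading": 0.0},
            index=[f"i{j}" for j in range(12)],
        )
        # construct differences equal to the standardized components
        stats_b = stats_a.copy()
        # shift so differences are the (already standardized) values
        stats_b["M"] = comp[:, 0]
        stats_b["r_it"] = comp[:, 1]
        stats_b["loading"] = comp[:, 2]
        table = csi_z(csi_compute(stats_a, stats_b))
        # |differences| are not mean-0/sd-1, so standardize what csi_z saw
        expected = sum(
            (table[c] - table[c].mean()) / table[c].std(ddof=1)
            for c in ("dM", "dr", "dlam")
        )
        pd.testing.assert_series_equal(
            table["CSI_z"], expected, check_names=False
        )

    def test_zero_variance_component_rejected(self):
        stats_a = pd.DataFrame(
            {"M": 0.0, "r_it": 0.0, "loading": 0.0}, index=list("abc")
        )
        stats_b = stats_a.copy()
        stats_b["M"] = [0.1, 0.1, 0.1]  # constant component
        stats_b["r_it"] = [0.1, 0.2, 0.3]
        stats_b["loading"] = [0.3, 0.2, 0.1]
        with pytest.raises(ValueError, match="zero variance"):
            csi_z(csi_compute(stats_a, stats_b))

    def test_equal_component_sds_give_identical_rankings(self):
        # components constructed with exactly equal across-item sds
        base = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        stats_a = pd.DataFrame(
            {"M": 0.0, "r_it": 0.0, "loading": 0.0},
            index=[f"i{j}" for j in range(5)],
        )
        stats_b = stats_a.copy()
        stats_b["M"] = base
        stats_b["r_it"] = base[::-1] * 0 + base  # same spread
        stats_b["loading"] = base
        table = csi_z(csi_compute(stats_a, stats_b))
        assert list(table["rank"]) == list(table["rank_z"])


class TestRankAgreement:
    def test_identical_and_reversed(self):
        v = np.arange(1, 8)
        same = rank_agreement(v, v)
        assert same["spearman_rho"] == pytest.approx(1.0)
        assert same["kendall_tau_b"] == pytest.approx(1.0)
        rev = rank_agreement(v, v[::-1])
        assert rev["spearman_rho"] == pytest.approx(-1.0)
        assert rev["kendall_tau_b"] == pytest.approx(-1.0)

    def test_tau_b_by_pair_counting(self):
        # (1,2,3,4) vs (1,2,4,3): 5 concordant, 1 discordant of 6 pairs
        res = rank_agreement([1, 2, 3, 4], [1, 2, 4, 3])
        n_c = n_d = 0
        a, b = [1, 2, 3, 4], [1, 2, 4, 3]
        for i, j in itertools.combinations(range(4), 2):
            s = (a[j] - a[i]) * (b[j] - b[i])
            n_c += s > 0
            n_d += s < 0
        assert res["kendall_tau_b"] == pytest.approx((n_c - n_d) / 6)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            rank_agreement([1, 1, 1], [1, 2, 3])


class TestTopK:
    def test_published_top_three_order(self, sdas_design_focal):
        zero, diff = table7_item_stats()
        table = csi_compute(zero, diff, design=None)
        top = top_k_report(table, 3)
        assert top["top_items"] == ["SDAS_27", "SDAS_03", "SDAS_04"]

    def test_position_tiebreak_is_deterministic(self):
        stats_a = pd.DataFrame(
            {"M": 0.0, "r_it": 0.0, "loading": 0.0},
            index=[f"i{j}" for j in range(4)],
        )
        table = csi_compute(stats_a, stats_a)
        top = top_k_report(table, 4)
        assert top["top_items"] == [f"i{j}" for j in range(4)]

    def test_reverse_share_and_adjacent_item(self, recoded_default,
                                             default_study):
        from carescreen.impact import compute_item_stats

        design = default_study.design
        attentive = default_study.truth_labels == "attentive"
        uns = recoded_default.data[list(design.scored_items)]
        scr = recoded_default.data.loc[attentive, list(design.scored_items)]
        table = csi_compute(
            compute_item_stats(uns, design),
            compute_item_stats(scr, design),
            design,
        )
        top = top_k_report(table, 10)
        assert top["n_reverse_total"] == 6
        assert top["item_after_instructed"] == "SDAS_27"
        # acquiescent-dominant contamination concentrates sensitivity in
        # reverse-worded items: over-represented relative to their share
        assert top["n_reverse_in_top_k"] / 10 > 6 / 36
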