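"""Careless indicators: instructed check, longstring, even-odd, cuts."""

import numpy as np
import pandas as pd
import pytest

from carescreen.design import ResponseMatrix, recode_reverse, scale_scores
from carescreen.screen import (
    evenodd_index,
    extended_flags,
    flag_instructed,
    longstring_index,
    outlier_flag,
    screen_study,
    split_samples,
)
from carescreen.simulate import assemble_study, default_sdas_config


def brute_force_longstring(row: np.ndarray) -> int:
    best = run = 1
    for j in range(1, len(row)):
        run = run + 1 if row[j] == row[j - 1] else 1
        best = max(best, run)
    return best


def brute_force_evenodd(matrix, design):
    """Independent straight-line implementation of the even-odd index."""
    out = []
    for _, row in matrix.data.iterrows():
        odd, even = [], []
        for factor in design.factors:
            items = design.factor_items(factor)
            odd.append(np.mean([row[i] for i in items[0::2]]))
            even.append(np.mean([row[i] for i in items[1::2]]))
        odd, even = np.array(odd), np.array(even)
        if odd.std() == 0 or even.std() == 0:
            out.append(2.0)
            continue
        r = np.corrcoef(odd, even)[0, 1]
        r = min(max(r, -0.999), 1.0)
        r_sb = min(max(2 * r / (1 + r), -1.0), 1.0)
        out.append(1.0 - r_sb)
    return np.array(out)


class TestInstructedFlag:
    def test_required_category_not_flagged(self, sdas_design_focal):
        data = pd.DataFrame([[3] * 37, [4] * 37],
                            columns=list(sdas_design_focal.item_ids))
        flags = flag_instructed(ResponseMatrix(data), sdas_design_focal)
        assert list(flags) == [False, True]

    def test_archetypes_never_emitting_required_all_flagged(self):
        """All-acquiescent careless mix never hits the midpoint, so the
        primary flag count equals the planted careless count exactly."""
        cfg = default_sdas_config(
            seed=17, n_respondents=1112, prevalence=0.1133,
            include_criteria=False, archetype_mix={"acquiescent": 1.0},
        )
        study = assemble_study(cfg)
        flags = flag_instructed(study.matrix, study.design)
        assert int(flags.sum()) == 126
        assert 100 * flags.mean() == pytest.approx(11.33, abs=0.005)

    def test_missing_column_errors(self, sdas_design_focal):
        data = pd.DataFrame([[3] * 36],
                            columns=[c for c in sdas_design_focal.item_ids
                                     if c != "SDAS_26"])
        with pytest.raises(ValueError, match="SDAS_26"):
            flag_instructed(ResponseMatrix(data), sdas_design_focal)


class TestLongstring:
    def test_hand_examples(self):
        data = pd.DataFrame([[1, 1, 1, 2, 2], [7, 7, 7, 7, 7]])
        ls = longstring_index(ResponseMatrix(data))
        assert list(ls) == [3, 5]

    def test_constant_row_equals_battery_length(self, sdas_design_focal):
        data = pd.DataFrame([[2] * 37],
                            columns=list(sdas_design_focal.item_ids))
        assert longstring_index(ResponseMatrix(data)).iloc[0] == 37

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(4242)
        data = pd.DataFrame(rng.integers(1, 6, size=(1000, 65)))
        ls = longstring_index(ResponseMatrix(data)).to_numpy()
        oracle = np.array([brute_force_longstring(r)
                           for r in data.to_numpy()])
        assert np.array_equal(ls, oracle)


class TestEvenOdd:
    def test_perfectly_consistent_scores_zero(self, sdas_design_focal):
        # identical odd and even half-means per factor, variance across
        # factors > 0: build rows constant within factor, distinct across
        data = pd.DataFrame(
            [
                {i: {"economy": 1, "society": 3, "environment": 5}[
                    sdas_design_focal.factor_map.get(i, "economy")]
                 for i in sdas_design_focal.item_ids}
            ]
        )[list(sdas_design_focal.item_ids)]
        idx = evenodd_index(ResponseMatrix(data), sdas_design_focal)
        assert idx.iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_half_means_score_two(self, sdas_design_focal):
        """Half-mean pairs (5,1), (1,5), (3,3) give r = -1, hence the
        maximal inconsistency score 2 after the Spearman-Brown step."""
        row = {}
        for factor, (o, e) in {
            "economy": (5, 1), "society": (1, 5), "environment": (3, 3)
        }.items():
            items = sdas_design_focal.factor_items(factor)
            for pos, item in enumerate(items):
                row[item] = o if pos % 2 == 0 else e
        row["SDAS_26"] = 3
        data = pd.DataFrame([row])[list(sdas_design_focal.item_ids)]
        idx = evenodd_index(ResponseMatrix(data), sdas_design_focal)
        assert idx.iloc[0] == pytest.approx(2.0)

    def test_straightliner_assigned_maximal_inconsistency(
        self, sdas_design_focal
    ):
        data = pd.DataFrame([[4] * 37],
                            columns=list(sdas_design_focal.item_ids))
        idx = evenodd_index(ResponseMatrix(data), sdas_design_focal)
        assert idx.iloc[0] == 2.0

    def test_fewer_than_three_factors_rejected(self, minimal_design):
        data = pd.DataFrame({"a": [1], "b": [2]})
        with pytest.raises(ValueError, match="3 factors"):
            evenodd_index(ResponseMatrix(data), minimal_design)

    def test_matches_independent_implementation(self, small_study):
        recoded = recode_reverse(small_study.matrix, small_study.design)
        ours = evenodd_index(recoded, small_study.design).to_numpy()
        oracle = brute_force_evenodd(recoded, small_study.design)
        np.testing.assert_allclose(ours, oracle, atol=1e-12)


class TestOutlierFlag:
    def test_planted_extremes_flagged(self):
        rng = np.random.default_rng(11)
        scores = pd.Series(np.r_[rng.normal(100, 10, 1112), [500.0] * 7])
        flags = outlier_flag(scores, 4.0)
        assert int(flags.sum()) == 7
        assert int((~flags).sum()) == 1112

    def test_infinite_cut_flags_none(self):
        scores = pd.Series([1.0, 2.0, 3.0, 100.0])
        assert not outlier_flag(scores, np.inf).any()

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            outlier_flag(pd.Series([2.0, 2.0, 2.0]))


class TestExtendedFlags:
    def test_union_is_superset_of_primary(self, small_study):
        result = screen_study(small_study.matrix, small_study.design)
        assert (result.flag_extended | ~result.flag_primary).all()
        assert (result.flag_primary <= result.flag_extended).all()

    def test_cut_construction_and_index_only_flagging(self):
        instructed = pd.Series([False, False, False, False, False, True])
        longstring = pd.Series([3, 4, 3, 4, 30, 3])
        evenodd = pd.Series([0.1, 0.2, 0.1, 0.2, 0.15, 0.1])
        flags, ls_cut, eo_cut = extended_flags(instructed, longstring, evenodd)
        assert ls_cut == pytest.approx(
            longstring.mean() + 2 * longstring.std(ddof=1))
        assert flags.iloc[4] and not instructed.iloc[4]  # longstring-only
        assert flags.iloc[5]  # instructed failure always included

    def test_degenerate_distribution_rejected(self):
        instructed = pd.Series([False, True])
        const = pd.Series([3, 3])
        with pytest.raises(ValueError, match="degenerate"):
            extended_flags(instructed, const, pd.Series([0.1, 0.2]))


class TestSplitSamples:
    def test_partition_counts(self):
        cfg = default_sdas_config(
            seed=17, n_respondents=1112, prevalence=0.1133,
            include_criteria=False, archetype_mix={"acquiescent": 1.0},
        )
        study = assemble_study(cfg)
        flags = flag_instructed(study.matrix, study.design)
        uns, scr, car = split_samples(study.matrix, flags)
        assert (uns.n, scr.n, car.n) == (1112, 986, 126)
        assert set(scr.respondent_ids) | set(car.respondent_ids) == set(
            uns.respondent_ids
        )
        assert not set(scr.respondent_ids) & set(car.respondent_ids)

    def test_no_flags_screened_equals_unscreened(self, small_study):
        flags = pd.Series(False, index=small_study.matrix.data.index)
        uns, scr, car = split_samples(small_study.matrix, flags)
        assert scr.n == uns.n and car.n == 0

    def test_all_flagged_rejected(self, small_study):
        flags = pd.Series(True, index=small_study.matrix.data.index)
        with pytest.raises(ValueError, match="all respondents"):
            split_samples(small_study.matrix, flags)


class TestSingleCheckBlindSpot:
    def test_uniform_careless_partially_slip_through(self):
        """With a pure random-uniform careless mix the primary flag rate
        approximates prevalence * (1 - 1/#categories): one in five random
        responders lands on the required category by chance."""
        cfg = default_sdas_config(
            seed=23, n_respondents=4000, prevalence=0.10,
            include_criteria=False,
            archetype_mix={"random_uniform": 1.0},
        )
        study = assemble_study(cfg)
        flags = flag_instructed(study.matrix, study.design)
        expected = 0.10 * (1 - 1 / 5)
        assert flags.mean() == pytest.approx(expected, abs=0.015)
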