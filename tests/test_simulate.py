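"""Generator behavior: determinism, archetype support, moment targets.

The frozen constant ALPHA_ORACLE is the Cronbach's alpha of the
six-item, loading-0.7 graded model computed once by an independent
Monte-Carlo implementation at n = 10^6 (thresholds at the 0.1/0.3/0.7/0.9
normal quantiles); the generated data must reproduce it within
sampling error.
"""

import numpy as np
import pandas as pd
import pytest

from carescreen.design import ResponseMatrix, recode_reverse, scale_scores
from carescreen.reliability import cronbach_alpha
from carescreen.simulate import (
    SimConfig,
    assemble_study,
    default_sdas_config,
    simulate_attentive,
    simulate_careless,
)

# one-off large-n Monte-Carlo oracle value (see module docstring)
ALPHA_ORACLE = 0.830


class TestDeterminism:
    def test_same_seed_same_matrix(self, sdas_design_focal):
        cfg = default_sdas_config(seed=5, n_respondents=60,
                                  include_criteria=False)
        a = assemble_study(cfg).matrix.data
        b = assemble_study(cfg).matrix.data
        pd.testing.assert_frame_equal(a, b)

    def test_row_substreams_stable_under_row_count(self):
        cfg = default_sdas_config(seed=5, n_respondents=50, prevalence=0.0,
                                  include_criteria=False)
        small = simulate_attentive(cfg, 20)
        large = simulate_attentive(cfg, 40)
        pd.testing.assert_frame_equal(small, large.iloc[:20])


class TestAttentiveProcess:
    def test_zero_loadings_give_independent_items(self):
        items = tuple(f"q{j}" for j in range(6))
        from carescreen.design import SurveyDesign

        design = SurveyDesign(item_ids=items,
                              factor_map={i: "g" for i in items})
        cfg = SimConfig(
            design=design, n_respondents=5000, prevalence=0.0,
            loadings={i: 0.0 for i in items},
            factor_corr=np.array([[1.0]]), seed=77,
        )
        data = simulate_attentive(cfg, 5000)
        corr = np.corrcoef(data.to_numpy(float), rowvar=False)
        off = corr[np.triu_indices(6, 1)]
        assert np.max(np.abs(off)) < 0.05

    def test_alpha_matches_monte_carlo_oracle(self, one_factor_config):
        data = simulate_attentive(one_factor_config, 5000)
        assert cronbach_alpha(data) == pytest.approx(ALPHA_ORACLE, abs=0.03)

    def test_attentive_rows_pass_instructed_check(self, sdas_design_focal):
        cfg = default_sdas_config(seed=9, n_respondents=50, prevalence=0.0,
                                  include_criteria=False)
        data = simulate_attentive(cfg, 50)
        assert (data["SDAS_26"] == 3).all()

    def test_non_pd_factor_corr_rejected(self, sdas_design_focal):
        bad = np.array([[1.0, 1.2, 0.5], [1.2, 1.0, 0.5], [0.5, 0.5, 1.0]])
        with pytest.raises(ValueError, match="positive-definite"):
            default_sdas_config(factor_corr=bad)


class TestCarelessArchetypes:
    def test_acquiescent_support_is_top_two(self):
        cfg = default_sdas_config(seed=3, include_criteria=False)
        rows = simulate_careless(cfg, "acquiescent", 40)
        assert rows.to_numpy().min() >= 4
        # and the instructed check is therefore always failed
        assert (rows["SDAS_26"] != 3).all()

    def test_midpoint_straightliner_passes_check_with_full_run(self):
        cfg = default_sdas_config(seed=3, include_criteria=False)
        rows = simulate_careless(cfg, "midpoint_straightliner", 5)
        assert (rows.to_numpy() == 3).all()

    def test_random_uniform_pass_rate_near_one_fifth(self):
        cfg = default_sdas_config(seed=31, include_criteria=False)
        rows = simulate_careless(cfg, "random_uniform", 10_000)
        rate = float((rows["SDAS_26"] == 3).mean())
        assert rate == pytest.approx(0.20, abs=0.01)

    def test_fixed_straightliner_constant_within_block(self):
        cfg = default_sdas_config(seed=12, include_criteria=False)
        rows = simulate_careless(cfg, "fixed_straightliner", 10)
        assert (rows.nunique(axis=1) == 1).all()

    def test_late_onset_attentive_before_onset(self):
        cfg = default_sdas_config(seed=12, include_criteria=False)
        attentive = simulate_attentive(cfg, 10)
        late = simulate_careless(cfg, "late_onset", 10)
        before = list(cfg.design.battery_items[: cfg.onset_position - 1])
        pd.testing.assert_frame_equal(late[before], attentive[before])
        after = list(cfg.design.battery_items[cfg.onset_position - 1:])
        assert late[after].to_numpy().min() >= 4  # acquiescent tail

    def test_unknown_archetype(self):
        cfg = default_sdas_config(include_criteria=False)
        with pytest.raises(ValueError, match="unknown archetype"):
            simulate_careless(cfg, "telepathic", 3)


class TestAssembleStudy:
    def test_zero_prevalence_all_attentive(self):
        cfg = default_sdas_config(seed=8, n_respondents=80, prevalence=0.0,
                                  include_criteria=False)
        study = assemble_study(cfg)
        assert (study.truth_labels == "attentive").all()

    def test_careless_count_rounds_prevalence(self):
        cfg = default_sdas_config(seed=8, n_respondents=1112,
                                  prevalence=0.1133, include_criteria=False)
        study = assemble_study(cfg)
        assert study.n_careless_true == 126

    def test_archetype_mix_must_sum_to_one(self, sdas_design_focal):
        with pytest.raises(ValueError, match="sum to 1"):
            assemble_study(
                default_sdas_config(
                    n_respondents=100, include_criteria=False,
                    archetype_mix={"acquiescent": 0.5, "random_uniform": 0.2},
                )
            )

    def test_criterion_scores_attenuated_correlation(self):
        cfg = default_sdas_config(seed=21, n_respondents=5000, prevalence=0.0)
        study = assemble_study(cfg)
        recoded = recode_reverse(study.matrix, study.design)
        total = scale_scores(recoded, study.design, "total")
        psrs = study.matrix.data[
            [c for c in study.matrix.data.columns if c.startswith("PSRS")]
        ].sum(axis=1)
        r = float(np.corrcoef(total, psrs)[0, 1])
        # latent correlation 0.40, attenuated by both scales' reliability
        assert 0.25 < r < 0.40


class TestDefaultConfig:
    def test_reverse_positions_and_factor_sizes(self):
        cfg = default_sdas_config()
        d = cfg.design
        assert sorted(d.reverse_set) == [
            "SDAS_01", "SDAS_08", "SDAS_10", "SDAS_24", "SDAS_31", "SDAS_35"
        ]
        assert [len(d.factor_items(f)) for f in d.factors] == [13, 9, 14]
        assert d.required_category == 3
        loadings = cfg.resolved_loadings()
        assert np.mean(list(loadings.values())) == pytest.approx(0.57, abs=0.02)

    def test_reverse_item_mean_shift_dominates(self):
        """Acquiescent contamination moves recoded reverse-item means more
        than standard-item means (the wording-effect mechanism)."""
        hits = 0
        n_rep = 10
        for rep in range(n_rep):
            cfg = default_sdas_config(
                seed=1000 + rep, n_respondents=600, prevalence=0.1133,
                include_criteria=False,
            )
            study = assemble_study(cfg)
            recoded = recode_reverse(study.matrix, study.design)
            attentive = study.truth_labels == "attentive"
            scored = list(study.design.scored_items)
            all_means = recoded.data[scored].mean()
            att_means = recoded.data.loc[attentive, scored].mean()
            dm = (all_means - att_means).abs()
            rev = [i for i in scored if i in study.design.reverse_set]
            std = [i for i in scored if i not in study.design.reverse_set]
            if dm[rev].mean() > dm[std].mean():
                hits += 1
        assert hits >= 0.9 * n_rep
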