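"""Synthetic experiment generation, inclusion filtering, and dataset IO."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from collective_rescue.synth import (
    TABLE3_1R1S_POS_GROUP,
    ExperimentDesign,
    HierGlobals,
    apply_inclusion_filter,
    draw_individual_params,
    generate_experiment,
    read_dataset,
    stack_dataset,
    write_dataset,
)
from collective_rescue.tasks import make_preset_task


def _implied_mean(mu, s, transform):
    """Numerical-integration oracle for E[transform(mu + s Z)]."""
    f = lambda z: transform(mu + s * z) * stats.norm.pdf(z)
    val, _err = integrate.quad(f, -10, 10)
    return val


class TestParameterDraws:
    def test_draws_respect_supports(self, rng):
        df = draw_individual_params(TABLE3_1R1S_POS_GROUP, 2000, rng)
        assert ((df["alpha"] > 0) & (df["alpha"] < 1)).all()
        assert ((df["sigma"] > 0) & (df["sigma"] < 1)).all()
        assert (df["beta"] > 0).all()
        assert np.isfinite(df["theta"]).all()

    def test_sample_means_match_implied_means(self, rng):
        g = TABLE3_1R1S_POS_GROUP
        df = draw_individual_params(g, 2000, rng)
        expit = lambda x: 1 / (1 + np.exp(-x))
        targets = {
            "alpha": _implied_mean(g.mu_logit_alpha, g.s_alpha, expit),
            "beta": _implied_mean(g.mu_log_beta, g.s_beta, np.exp),
            "sigma": _implied_mean(g.mu_logit_sigma, g.s_sigma, expit),
            "theta": g.mu_theta,
        }
        for name, target in targets.items():
            se = df[name].std() / np.sqrt(len(df))
            assert abs(df[name].mean() - target) <= 3 * se

    def test_solo_condition_draws_are_asocial(self, rng):
        df = draw_individual_params(TABLE3_1R1S_POS_GROUP, 50, rng, social=False)
        assert (df["sigma"] == 0).all()

    def test_zero_spread_collapses_to_point(self, rng):
        g = HierGlobals(
            mu_logit_alpha=-2.0, mu_log_beta=1.0, mu_logit_sigma=-2.0, mu_theta=1.5,
            s_alpha=0.0, s_beta=0.0, s_sigma=0.0, s_theta=0.0,
        )
        df = draw_individual_params(g, 10, rng)
        assert df.nunique().max() == 1


class TestGenerateExperiment:
    def test_solo_only_design(self):
        design = ExperimentDesign(n_groups=0, n_individual=5, seed=3)
        data, truth = generate_experiment(design)
        assert data["subject_id"].nunique() == 5
        assert (data["condition"] == "individual").all()
        assert (truth["sigma"] == 0).all()

    def test_group_counts_sum_to_others(self):
        design = ExperimentDesign(n_groups=3, group_sizes=(4,), seed=5)
        data, truth = generate_experiment(design)
        assert truth["subject_id"].nunique() == 12
        later = data[data["trial"] > 1]
        k_cols = [c for c in data.columns if c.startswith("count_option_")]
        assert (later[k_cols].sum(axis=1) == 3).all()

    def test_reproducible_given_seed(self):
        design = ExperimentDesign(n_groups=2, group_sizes=(3,), seed=11)
        d1, t1 = generate_experiment(design)
        d2, t2 = generate_experiment(design)
        pd.testing.assert_frame_equal(d1, d2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_dropout_hazard_truncates_subjects(self):
        design = ExperimentDesign(
            n_groups=0, n_individual=200, dropout_hazard=0.02, seed=9
        )
        data, truth = generate_experiment(design)
        counts = data.groupby("subject_id")["trial"].count()
        assert (counts < 70).any()
        merged = truth.set_index("subject_id")["completed"]
        for sid, c in counts.items():
            assert c == merged[sid]

    def test_dropout_filter_induces_no_parameter_selection(self):
        """The hazard is behaviour-independent, so the inclusion filter
        leaves the parameter distribution unchanged (within noise)."""
        design = ExperimentDesign(
            n_groups=0, n_individual=400, dropout_hazard=0.02, seed=13
        )
        data, truth = generate_experiment(design)
        kept, removed = apply_inclusion_filter(data)
        assert len(removed) > 10
        kept_alpha = truth[truth["subject_id"].isin(kept["subject_id"].unique())]["alpha"]
        p = stats.ttest_ind(kept_alpha, truth["alpha"]).pvalue
        assert p > 0.01

    def test_invalid_designs_rejected(self):
        with pytest.raises(ValueError):
            ExperimentDesign(trials=0)
        with pytest.raises(ValueError):
            ExperimentDesign(group_sizes=(9,))
        with pytest.raises(ValueError):
            ExperimentDesign(dropout_hazard=1.0)


class TestInclusionFilter:
    @staticmethod
    def _data(completed_by_subject):
        rows = []
        for sid, n in completed_by_subject.items():
            for t in range(1, n + 1):
                rows.append(
                    {
                        "subject_id": sid, "group_id": 0, "condition": "group",
                        "task": "exp_1r1s_pos", "trial": t, "choice": 0, "payoff": 150.0,
                        "count_option_1": 0, "count_option_2": 0,
                    }
                )
        return pd.DataFrame(rows)

    def test_boundary_at_35_rounds(self):
        data = self._data({1: 34, 2: 35, 3: 70})
        kept, removed = apply_inclusion_filter(data)
        assert removed == [1]
        assert set(kept["subject_id"]) == {2, 3}

    def test_no_dropout_is_identity(self):
        data = self._data({1: 70, 2: 70})
        kept, removed = apply_inclusion_filter(data)
        assert removed == []
        pd.testing.assert_frame_equal(kept.reset_index(drop=True), data)

    def test_all_removed_warns(self):
        data = self._data({1: 10, 2: 5})
        with pytest.warns(UserWarning):
            kept, removed = apply_inclusion_filter(data)
        assert len(kept) == 0
        assert removed == [1, 2]


class TestDatasetIO:
    def test_round_trip(self, tmp_path):
        design = ExperimentDesign(n_groups=1, group_sizes=(3,), seed=2)
        data, truth = generate_experiment(design)
        path = str(tmp_path / "d.csv")
        write_dataset(path, data, truth)
        data2, truth2 = read_dataset(path)
        pd.testing.assert_frame_equal(data, data2, check_dtype=False)
        pd.testing.assert_frame_equal(truth, truth2, check_dtype=False)

    def test_missing_column_named_in_error(self, tmp_path):
        design = ExperimentDesign(n_groups=1, group_sizes=(2,), seed=2)
        data, _ = generate_experiment(design)
        path = str(tmp_path / "d.csv")
        write_dataset(path, data.drop(columns=["payoff"]))
        with pytest.raises(ValueError, match="payoff"):
            read_dataset(path)

    def test_extra_columns_preserved(self, tmp_path):
        design = ExperimentDesign(n_groups=1, group_sizes=(2,), seed=2)
        data, _ = generate_experiment(design)
        data["note"] = "x"
        path = str(tmp_path / "d.csv")
        write_dataset(path, data)
        data2, _ = read_dataset(path)
        assert "note" in data2.columns


class TestStacking:
    def test_stacked_shapes_and_missing_markers(self):
        design = ExperimentDesign(
            n_groups=2, group_sizes=(3,), n_individual=2, dropout_hazard=0.05, seed=21
        )
        data, truth = generate_experiment(design)
        data, _ = apply_inclusion_filter(data, min_rounds=1)
        task = make_preset_task("exp_1r1s_pos")
        stacked = stack_dataset(data, task)
        n = data["subject_id"].nunique()
        assert stacked["choices"].shape == (n, int(data["trial"].max()))
        completed = data.groupby("subject_id")["trial"].count()
        for i, sid in enumerate(stacked["subject_ids"]):
            assert (stacked["choices"][i] >= 0).sum() == completed[sid]
        # payoffs are rescaled into learning units
        observed = stacked["payoffs"][stacked["choices"] >= 0]
        assert observed.max() < 10.0

    def test_stacking_requires_count_columns(self):
        task = make_preset_task("exp_1r1s_pos")
        df = pd.DataFrame(
            {"subject_id": [1], "trial": [1], "choice": [0], "payoff": [150.0]}
        )
        with pytest.raises(ValueError, match="count_option_1"):
            stack_dataset(df, task)
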