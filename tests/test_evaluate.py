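import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from swallowscreen.core import ConfigError, Consistency, DataError, PipelineConfig
from swallowscreen.evaluate import (
    SampleSizeResult,
    UndefinedAUCError,
    make_split,
    monte_carlo_evaluate,
    operating_point,
    participant_score,
    roc_auc,
    run_suite,
    suite_tasks,
    tables_report,
    validation_sample_size,
)
from swallowscreen.rlda import fit_rlda, predict_proba

from conftest import gaussian_feature_table


class TestMakeSplit:
    def test_stratification_arithmetic(self):
        status = {f"P{i}": (1 if i < 23 else 0) for i in range(100)}
        plan = make_split(status, 0.2, np.random.default_rng(0))
        assert len(plan.validation) == 20
        impaired_val = sum(status[p] for p in plan.validation)
        assert impaired_val in (4, 5)
        assert plan.training | plan.validation == set(status)
        assert not plan.training & plan.validation

    def test_deterministic_for_seed(self):
        status = {f"P{i}": i % 2 for i in range(50)}
        a = make_split(status, 0.2, np.random.default_rng(7))
        b = make_split(status, 0.2, np.random.default_rng(7))
        assert a == b

    @pytest.mark.parametrize("fraction", [0.0, 1.0])
    def test_bad_fraction(self, fraction):
        with pytest.raises(ConfigError):
            make_split({"a": 0, "b": 0}, fraction, np.random.default_rng(0))

    def test_singleton_stratum_goes_to_training(self):
        status = {"lone": 1, **{f"P{i}": 0 for i in range(10)}}
        plan = make_split(status, 0.2, np.random.default_rng(1))
        assert "lone" in plan.training

    @given(st.integers(10, 80), st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=30)
    def test_stratum_proportions_preserved(self, n, seed):
        status = {f"P{i}": (1 if i < n // 3 else 0) for i in range(n)}
        plan = make_split(status, 0.2, np.random.default_rng(seed))
        for stratum in (0, 1):
            members = [p for p, s in status.items() if s == stratum]
            n_val = sum(1 for p in members if p in plan.validation)
            assert abs(n_val - 0.2 * len(members)) <= 1.0


class TestParticipantScore:
    def test_thin_caps_at_four(self, config):
        got = participant_score(
            [0.2, 0.4, 0.6, 0.8, 0.9, 0.9], Consistency.thin, config
        )
        assert got == pytest.approx(0.5)

    def test_up_to_three_allows_fewer(self, config):
        got = participant_score([0.3, 0.6], Consistency.mildly_thick, config)
        assert got == pytest.approx(0.45)

    def test_single_bolus(self, config):
        assert participant_score([0.7], Consistency.thin, config) == pytest.approx(0.7)

    def test_empty_is_missing(self, config):
        assert participant_score([], Consistency.thin, config) is None


def brute_force_auc(scores, labels):
    """Exhaustive pair counting with half credit for ties."""
    total = wins = 0.0
    for (sp, yp), (sn, yn) in itertools.product(
        zip(scores, labels), zip(scores, labels)
    ):
        if yp == 1 and yn == 0:
            total += 1
            if sp > sn:
                wins += 1
            elif sp == sn:
                wins += 0.5
    return wins / total


class TestRocAuc:
    def test_perfect_ranking(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties(self):
        assert roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_one_class_raises(self):
        with pytest.raises(UndefinedAUCError):
            roc_auc([0.1, 0.2], [1, 1])

    @given(st.integers(0, 2**31 - 1), st.integers(5, 40))
    @settings(deadline=None, max_examples=50)
    def test_pair_count_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        scores = rng.choice([0.1, 0.3, 0.5, 0.7], size=n)  # force ties
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        assert roc_auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12
        )


class TestOperatingPoint:
    def test_separable_full_sensitivity(self):
        scores = [0.1, 0.2, 0.8, 0.9]
        labels = [0, 0, 1, 1]
        t = operating_point(scores, labels, 0.6)
        preds = np.array(scores) >= t
        assert preds.tolist() == [False, False, True, True]

    def test_target_one_above_all_negatives(self):
        rng = np.random.default_rng(0)
        scores = np.concatenate([rng.normal(0, 1, 50), rng.normal(0.5, 1, 50)])
        labels = np.array([0] * 50 + [1] * 50)
        t = operating_point(scores, labels, 1.0)
        assert (scores[labels == 0] < t).all()

    def test_null_identity(self):
        # independent scores: validation sensitivity ~ 1 - specificity target
        rng = np.random.default_rng(1)
        n = 2_000
        train_scores = rng.uniform(size=n)
        train_labels = rng.integers(0, 2, size=n)
        t = operating_point(train_scores, train_labels, 0.6)
        val_scores = rng.uniform(size=n)
        val_labels = rng.integers(0, 2, size=n)
        sens = np.mean(val_scores[val_labels == 1] >= t)
        assert sens == pytest.approx(0.4, abs=0.05)

    def test_needs_both_classes(self):
        with pytest.raises(DataError):
            operating_point([0.1, 0.2], [1, 1], 0.6)


class TestMonteCarloEvaluate:
    def test_null_calibration(self, fast_config):
        # a single finite cohort carries chance structure (dataset-level SD
        # ~3 points), so the null is checked across regenerated cohorts:
        # 10 datasets x 25 iterations = 250 effect-free iterations
        cfg = fast_config.replace(n_iterations=25)
        means, weights = [], []
        for seed in range(10):
            table = gaussian_feature_table(n_participants=80, effect=0.0, seed=seed)
            res = monte_carlo_evaluate(
                table, "safety", cfg, consistency=Consistency.thin
            )
            means.append(res.bolus_auc_mean)
            weights.append(res.n_iterations)
        pooled = float(np.average(means, weights=weights))
        assert sum(weights) >= 200
        assert pooled == pytest.approx(50.0, abs=3.0)

    def test_separable(self, fast_config):
        table = gaussian_feature_table(n_participants=80, effect=5.0, seed=1)
        res = monte_carlo_evaluate(
            table, "safety", fast_config, consistency=Consistency.thin
        )
        assert res.bolus_auc_mean >= 97.0

    def test_same_seed_identical(self, fast_config):
        table = gaussian_feature_table(n_participants=40, effect=1.0, seed=2)
        cfg = fast_config.replace(n_iterations=50)
        a = monte_carlo_evaluate(table, "safety", cfg, consistency=Consistency.thin)
        b = monte_carlo_evaluate(table, "safety", cfg, consistency=Consistency.thin)
        assert a == b

    def test_single_iteration_matches_manual_run(self, config):
        table = gaussian_feature_table(n_participants=40, effect=1.5, seed=3)
        cfg = config.replace(n_iterations=1, seed=11, shrinkage=0.3)
        res = monte_carlo_evaluate(table, "safety", cfg, consistency=Consistency.thin)

        # manual re-run with the same seed
        rng = np.random.default_rng(11)
        status = {
            pid: int(g["safety_label"].max())
            for pid, g in table.groupby("participant_id")
        }
        plan = make_split(status, cfg.validation_fraction, rng)
        feat_cols = [c for c in table.columns if c.startswith("f")]
        train = table[table["participant_id"].isin(plan.training)]
        val = table[table["participant_id"].isin(plan.validation)]
        model = fit_rlda(
            train[feat_cols].to_numpy(),
            train["safety_label"].to_numpy(dtype=int),
            shrinkage=0.3,
            feature_names=feat_cols,
        )
        probs = predict_proba(model, val[feat_cols].to_numpy())
        manual_auc = 100.0 * roc_auc(probs, val["safety_label"].to_numpy(dtype=int))
        assert res.bolus_auc_mean == pytest.approx(manual_auc, abs=1e-9)
        assert res.bolus_auc_sd == 0.0

    def test_participant_auc_beats_bolus_auc_directionally(self, fast_config):
        wins = 0
        n_rep = 20
        cfg = fast_config.replace(n_iterations=40)
        for seed in range(n_rep):
            table = gaussian_feature_table(
                n_participants=60, n_boluses=4, effect=1.0, seed=seed
            )
            res = monte_carlo_evaluate(
                table, "safety", cfg, consistency=Consistency.thin
            )
            if res.participant_auc_mean >= res.bolus_auc_mean:
                wins += 1
        assert wins >= 0.7 * n_rep

    def test_capped_scoring_uses_protocol_order(self, fast_config):
        # boluses beyond the cap carry pure noise: results must not change
        cfg = fast_config.replace(n_iterations=30)
        table = gaussian_feature_table(n_participants=40, n_boluses=4, effect=2.0, seed=5)
        res4 = monte_carlo_evaluate(table, "safety", cfg, consistency=Consistency.thin)
        extra = table[table["bolus_index"] == 4].copy()
        extra["bolus_index"] = 5
        feat_cols = [c for c in table.columns if c.startswith("f")]
        rng = np.random.default_rng(0)
        extra[feat_cols] = rng.normal(size=extra[feat_cols].shape)
        res5 = monte_carlo_evaluate(
            pd.concat([table, extra], ignore_index=True),
            "safety",
            cfg,
            consistency=Consistency.thin,
        )
        assert res5.participant_auc_mean == pytest.approx(res4.participant_auc_mean)


class TestSuite:
    def test_six_tasks(self):
        tasks = suite_tasks()
        assert len(tasks) == 6
        combined = [t for t in tasks if t[2]]
        assert len(combined) == 1
        assert combined[0][0] == Consistency.moderately_thick
        assert combined[0][1] == "safety"

    def test_combined_training_structure(self, fast_config):
        cfg = fast_config.replace(n_iterations=20)
        frames = []
        for consistency in (Consistency.moderately_thick, Consistency.extremely_thick):
            frames.append(
                gaussian_feature_table(
                    n_participants=40,
                    n_boluses=3,
                    effect=2.0,
                    seed=6,
                    consistency=consistency,
                )
            )
        table = pd.concat(frames, ignore_index=True)
        results = run_suite(None, cfg, feature_table=table)
        mod_safety = [
            r
            for r in results
            if r.consistency == "moderately_thick" and r.outcome == "safety"
        ][0]
        assert "extremely_thick" in mod_safety.training_consistencies
        assert mod_safety.validation_consistencies == ("moderately_thick",)

    def test_suite_without_extreme_degrades(self, fast_config):
        cfg = fast_config.replace(n_iterations=10)
        table = gaussian_feature_table(
            n_participants=40, n_boluses=3, effect=2.0, seed=7,
            consistency=Consistency.moderately_thick,
        )
        results = run_suite(None, cfg, feature_table=table)
        mod_safety = [
            r
            for r in results
            if r.consistency == "moderately_thick" and r.outcome == "safety"
        ][0]
        assert mod_safety.training_consistencies == ("moderately_thick",)

    def test_report_shape(self, fast_config):
        cfg = fast_config.replace(n_iterations=10)
        table = gaussian_feature_table(n_participants=40, effect=2.0, seed=8)
        results = run_suite(None, cfg, feature_table=table)
        report = tables_report(results)
        assert list(report.columns[:2]) == ["consistency", "outcome"]
        assert "±" in report["bolus_auc"].iloc[0]


class TestSampleSize:
    def test_monotone_in_power(self):
        kw = dict(
            prevalence=0.6,
            per_swallow_display_rate=0.3,
            n_boluses=4,
            sens_target=0.86,
            spec_target=0.60,
        )
        n80 = validation_sample_size(power=0.8, **kw).n_required
        n90 = validation_sample_size(power=0.9, **kw).n_required
        n95 = validation_sample_size(power=0.95, **kw).n_required
        assert n80 <= n90 <= n95

    def test_prevalence_limit(self):
        kw = dict(
            per_swallow_display_rate=0.99,
            n_boluses=4,
            sens_target=0.86,
            spec_target=0.60,
            power=0.9,
        )
        near_one = validation_sample_size(prevalence=0.999, **kw)
        # the positive arm approaches the positives-only requirement
        assert near_one.n_required_sensitivity == pytest.approx(
            near_one.assumptions["positives_needed"], abs=2
        )
        assert (
            near_one.n_required_sensitivity
            <= validation_sample_size(prevalence=0.5, **kw).n_required_sensitivity
        )

    def test_worked_defaults_logged(self):
        res = validation_sample_size(
            prevalence=0.60,
            per_swallow_display_rate=0.30,
            n_boluses=4,
            sens_target=0.86,
            spec_target=0.60,
            power=0.90,
        )
        assert isinstance(res, SampleSizeResult)
        assert res.n_required > 0
        assert res.evaluable_positive_fraction == pytest.approx(1 - 0.7**4)
        assert set(res.assumptions) >= {
            "prevalence",
            "sens_target",
            "spec_target",
            "power",
            "alpha",
            "null_margin",
        }

    def test_infeasible_targets(self):
        with pytest.raises(ConfigError):
            validation_sample_size(
                prevalence=0.6,
                per_swallow_display_rate=0.3,
                n_boluses=4,
                sens_target=1.5,
                spec_target=0.6,
            )
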