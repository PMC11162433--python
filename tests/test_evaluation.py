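import numpy as np
import pandas as pd
import pytest

from ionnet.evaluation import (
    PhenotypeTable,
    classification_metrics,
    contextualize,
    global_pool_pearson,
    intra_country_pearson,
    make_cv_plan,
    pearson_upper_bound,
    simpson_diagnostic,
)
from ionnet.synthetic import generate_simpson_dataset


def two_group_simpson(n_per_group=200, seed=0):
    """Between-group slope, no within-group signal."""
    x, table = generate_simpson_dataset(
        n_groups=2, between_slope=2.0, within_signal=0.0,
        n_per_group=n_per_group, seed=seed,
    )
    return x, table


class TestCVPlan:
    def test_random_kfold_partitions(self):
        ids = [f"s{i}" for i in range(10)]
        plan = make_cv_plan(ids, "random-kfold", k=5, seed=0)
        sizes = [len(f) for f in plan.folds]
        assert sizes == [2] * 5
        assert sorted(s for f in plan.folds for s in f) == sorted(ids)

    def test_country_stratified_greedy_example(self):
        ids = [f"s{i}" for i in range(10)]
        countries = ["A"] * 6 + ["B"] * 3 + ["C"]
        plan = make_cv_plan(ids, "country-stratified", k=2, seed=0, countries=countries)
        by_fold = [
            {countries[ids.index(s)] for s in fold} for fold in plan.folds
        ]
        assert {"A"} in by_fold
        assert {"B", "C"} in by_fold

    def test_stratified_never_splits_country(self):
        rng = np.random.default_rng(0)
        for seed in range(100):
            n = 60
            countries = rng.choice(list("ABCDEFGH"), size=n).tolist()
            ids = [f"s{i}" for i in range(n)]
            plan = make_cv_plan(
                ids, "country-stratified", k=3, seed=seed, countries=countries
            )
            plan.validate(countries=dict(zip(ids, countries)))

    def test_tl_leakage_safe_property(self):
        ids = [f"s{i}" for i in range(37)]
        for seed in range(100):
            plan = make_cv_plan(ids, "tl-leakage-safe", k=5, seed=seed)
            for fold in range(plan.k):
                test = set(plan.test_ids(fold))
                t1 = set(plan.t1_train_ids(fold))
                assert not (test & t1)
                assert test | t1 == set(ids)

    def test_fewer_countries_than_folds_rejected(self):
        with pytest.raises(ValueError, match="countries"):
            make_cv_plan(
                ["a", "b", "c"], "country-stratified", k=3, seed=0,
                countries=["X", "X", "Y"],
            )

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            make_cv_plan(["a", "b"], "random-kfold", k=5)


class TestIntraCountryPearson:
    def test_perfect_predictions(self, rng):
        obs = rng.standard_normal((40, 3))
        countries = np.array(["A"] * 20 + ["B"] * 20)
        report = intra_country_pearson(obs, obs, countries, min_n=5)
        assert np.allclose(report.per_country["r"], 1.0)
        assert np.allclose(report.intra_country_mean, 1.0)

    def test_three_point_closed_form(self):
        pred = np.array([[1.0], [2.0], [3.0]] * 20)
        obs = np.array([[1.0], [2.0], [4.0]] * 20)
        report = intra_country_pearson(pred, obs, ["A"] * 60, min_n=5)
        assert report.intra_country_mean.iloc[0] == pytest.approx(0.9819805, abs=1e-4)

    def test_constant_predictor_excluded_with_warning(self):
        rng = np.random.default_rng(0)
        obs = rng.standard_normal((40, 1))
        obs[:20] += 5.0
        pred = np.where(np.arange(40)[:, None] < 20, 5.0, 0.0)  # per-country constant
        countries = np.array(["A"] * 20 + ["B"] * 20)
        with pytest.warns(UserWarning, match="undefined"):
            report = intra_country_pearson(pred, obs, countries, min_n=5)
        assert report.intra_country_mean.isna().all()
        # but the pooled correlation is high: the Simpson construction
        assert global_pool_pearson(pred, obs).iloc[0] > 0.5

    def test_min_n_strictly_greater(self, rng):
        obs = rng.standard_normal((100, 1))
        pred = obs + 0.1 * rng.standard_normal((100, 1))
        countries = np.array(["A"] * 50 + ["B"] * 50)
        with pytest.warns(UserWarning, match="min_n"):
            report = intra_country_pearson(pred, obs, countries, min_n=50)
        assert len(report.per_country) == 0
        report2 = intra_country_pearson(pred, obs, countries, min_n=49)
        assert set(report2.per_country["country"]) == {"A", "B"}

    def test_unweighted_mean_over_countries(self, rng):
        obs = rng.standard_normal((30, 1))
        pred = obs.copy()
        pred[:20] += 0.5 * rng.standard_normal((20, 1))  # degrade country A only
        countries = np.array(["A"] * 20 + ["B"] * 10)
        report = intra_country_pearson(pred, obs, countries, min_n=5)
        per = report.per_country.set_index("country")["r"]
        assert report.intra_country_mean.iloc[0] == pytest.approx(
            (per["A"] + per["B"]) / 2
        )

    def test_relabeling_and_affine_invariance(self, rng):
        obs = rng.standard_normal((60, 2))
        pred = obs + 0.3 * rng.standard_normal((60, 2))
        countries = np.array(["A"] * 30 + ["B"] * 30)
        base = intra_country_pearson(pred, obs, countries, min_n=5).intra_country_mean
        relabel = np.where(countries == "A", "Z", "Q")
        m2 = intra_country_pearson(pred, obs, relabel, min_n=5).intra_country_mean
        np.testing.assert_allclose(base, m2)
        pred2, obs2 = pred.copy(), obs.copy()
        pred2[countries == "A"] = 3.0 * pred2[countries == "A"] + 1.0
        obs2[countries == "B"] = 0.5 * obs2[countries == "B"] - 2.0
        m3 = intra_country_pearson(pred2, obs2, countries, min_n=5).intra_country_mean
        np.testing.assert_allclose(base, m3, atol=1e-12)


class TestGlobalPoolPearson:
    def test_identity_and_negation(self, rng):
        obs = rng.standard_normal((20, 2))
        assert np.allclose(global_pool_pearson(obs, obs), 1.0)
        assert np.allclose(global_pool_pearson(-obs, obs), -1.0)

    def test_simpson_construction_gap(self):
        x, table = two_group_simpson()
        groups = table.countries
        # group-mean predictor: constant within each group
        pred = np.zeros_like(table.values)
        for g in np.unique(groups):
            pred[groups == g] = table.values[groups == g].mean()
        assert global_pool_pearson(pred, table.values).iloc[0] >= 0.8
        intra = intra_country_pearson(
            pred, table.values, groups, min_n=10
        ).intra_country_mean
        assert intra.isna().all() or np.nanmax(np.abs(intra)) <= 0.1


class TestPearsonUpperBound:
    def test_zero_replicate_spread_gives_one(self, rng):
        base = rng.standard_normal(20)
        reps = np.tile(base[:, None], (1, 4))
        assert pearson_upper_bound(reps) == 1.0

    def test_pure_noise_floored_to_zero(self, rng):
        # identical per-sample means but nonzero replicate spread:
        # observed signal variance is 0, so the floor engages exactly
        spread = rng.uniform(0.5, 2.0, size=50)
        reps = np.stack([-spread, spread], axis=1)
        assert pearson_upper_bound(reps) == 0.0

    def test_monte_carlo_oracle(self):
        # perfect predictor vs replicate-mean labels; noise sd 0.8, R=6
        rng = np.random.default_rng(42)
        n, r, sd = 2000, 6, 0.8
        truth = rng.standard_normal(n)
        reps = truth[:, None] + rng.normal(0.0, sd, size=(n, r))
        labels = reps.mean(axis=1)
        empirical = np.corrcoef(truth, labels)[0, 1]
        bound = pearson_upper_bound(reps)
        assert bound == pytest.approx(empirical, abs=0.02)

    def test_monotone_in_noise(self):
        rng = np.random.default_rng(1)
        truth = rng.standard_normal(500)
        bounds = []
        for sd in [0.2, 0.5, 1.0, 2.0]:
            reps = truth[:, None] + rng.normal(0.0, sd, size=(500, 6))
            bounds.append(pearson_upper_bound(reps))
        assert all(b < a for a, b in zip(bounds, bounds[1:]))

    def test_varying_replicate_counts(self, rng):
        reps = rng.standard_normal((30, 5))
        reps[::2, 3:] = np.nan  # some samples have fewer replicates
        assert 0.0 <= pearson_upper_bound(reps) <= 1.0

    def test_too_few_replicates_rejected(self, rng):
        reps = rng.standard_normal((10, 1))
        with pytest.raises(ValueError):
            pearson_upper_bound(reps)


class TestSimpsonDiagnostic:
    def test_perfect_prediction_no_flag(self, rng):
        obs = rng.standard_normal((60, 2))
        groups = np.array(["A"] * 30 + ["B"] * 30)
        diag = simpson_diagnostic(obs, obs, groups)
        assert np.allclose(diag["gap"], 0.0, atol=1e-12)
        assert not diag["flagged"].any()

    def test_constructed_dataset_flagged(self):
        x, table = two_group_simpson()
        groups = table.countries
        pred = np.zeros_like(table.values)
        for g in np.unique(groups):
            pred[groups == g] = table.values[groups == g].mean() + 1e-9 * x[groups == g]
        diag = simpson_diagnostic(pred, table.values, groups)
        assert diag["flagged"].all()

    def test_single_group_zero_gap(self, rng):
        obs = rng.standard_normal((30, 1))
        pred = obs + 0.2 * rng.standard_normal((30, 1))
        diag = simpson_diagnostic(pred, obs, ["A"] * 30)
        assert np.allclose(diag["gap"], 0.0)


class TestClassificationMetrics:
    def test_perfect_diagonal(self):
        f1, mcc = classification_metrics(np.diag([5, 7, 9]))
        assert f1 == 1.0
        assert mcc == pytest.approx(1.0)

    def test_uniform_confusion_zero_mcc(self):
        f1, mcc = classification_metrics(np.full((3, 3), 4))
        assert mcc == pytest.approx(0.0)

    def test_two_class_closed_form(self):
        # brute-force oracle: [[8,2],[1,9]] -> MCC 0.70352, macro F1 0.84962
        f1, mcc = classification_metrics(np.array([[8, 2], [1, 9]]))
        assert mcc == pytest.approx(0.7035, abs=1e-4)
        assert f1 == pytest.approx(0.84962, abs=1e-4)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            classification_metrics(np.zeros((2, 2)))

    def test_sklearn_agreement(self):
        from sklearn.metrics import f1_score, matthews_corrcoef

        rng = np.random.default_rng(0)
        true = rng.integers(0, 4, 300)
        pred = np.where(rng.random(300) < 0.6, true, rng.integers(0, 4, 300))
        conf = np.zeros((4, 4), dtype=int)
        np.add.at(conf, (true, pred), 1)
        f1, mcc = classification_metrics(conf)
        assert f1 == pytest.approx(f1_score(true, pred, average="macro"))
        assert mcc == pytest.approx(matthews_corrcoef(true, pred))


class TestContextualize:
    def test_percentages(self, rng):
        obs = rng.standard_normal((40, 3))
        pred = obs.copy()
        countries = np.array(["A"] * 40)
        report = intra_country_pearson(pred, obs, countries, min_n=5)
        report.intra_country_mean[:] = [0.42, 0.0, 0.21]
        bounds = pd.Series([0.42, 0.42, 0.42], index=report.intra_country_mean.index)
        out = contextualize(report, bounds)
        assert out.pct_of_bound.iloc[0] == pytest.approx(100.0)
        assert out.pct_of_bound.iloc[1] == pytest.approx(0.0)
        assert out.pct_of_bound.iloc[2] == pytest.approx(50.0)

    def test_exceeding_bound_flagged_not_clipped(self, rng):
        obs = rng.standard_normal((40, 1))
        report = intra_country_pearson(obs, obs, ["A"] * 40, min_n=5)
        bounds = pd.Series([0.5], index=report.intra_country_mean.index)
        with pytest.warns(UserWarning, match="exceed"):
            out = contextualize(report, bounds)
        assert out.pct_of_bound.iloc[0] == pytest.approx(200.0)

    def test_zero_bound_undefined(self, rng):
        obs = rng.standard_normal((40, 1))
        report = intra_country_pearson(obs, obs, ["A"] * 40, min_n=5)
        bounds = pd.Series([0.0], index=report.intra_country_mean.index)
        with pytest.warns(UserWarning, match="zero ceiling"):
            out = contextualize(report, bounds)
        assert np.isnan(out.pct_of_bound.iloc[0])


class TestPhenotypeTableIO:
    def test_csv_roundtrip_with_replicates(self, rng, tmp_path):
        n, t, r = 6, 3, 4
        reps = rng.standard_normal((n, t, r))
        reps[0, 0, 3] = np.nan
        table = PhenotypeTable(
            sample_ids=tuple(f"s{i}" for i in range(n)),
            values=np.nanmean(reps, axis=2),
            task_names=("Se82_leaf", "Se82_seed", "Mo98_leaf"),
            countries=np.array(["A", "A", "B", "B", "C", "C"]),
            lat=rng.uniform(30, 60, n),
            lon=rng.uniform(-10, 40, n),
            replicates=reps,
        )
        table.to_csv(tmp_path / "phen.csv")
        table.replicates_to_csv(tmp_path / "reps.csv")
        back = PhenotypeTable.from_csv(tmp_path / "phen.csv", tmp_path / "reps.csv")
        np.testing.assert_allclose(back.values, table.values, atol=1e-12)
        np.testing.assert_allclose(back.replicates, table.replicates, atol=1e-12)
        assert back.task_names == table.task_names
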