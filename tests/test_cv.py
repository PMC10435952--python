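import numpy as np
import pandas as pd
import pytest

import paireval as pe
from paireval.errors import (ConfigurationError, CoverageError, InputError,
                             PairedEvalError)


class OracleAdapter:
    """Scores each sample by a fixed function of its first feature."""

    def __init__(self, fn=lambda x: x):
        self.fn = fn

    def fit(self, X, y, seed):
        return None

    def score(self, state, X):
        return np.array([self.fn(row[0]) for row in np.asarray(X)])

    def importances(self, state):
        return None


class LeakageProbe(OracleAdapter):
    """Records every training set to assert held-out samples never leak."""

    def __init__(self):
        super().__init__()
        self.training_sets = []

    def fit(self, X, y, seed):
        self.training_sets.append(np.asarray(X)[:, 0].copy())
        return None


@pytest.fixture
def dataset(rng):
    # first feature IS the label; remaining features are noise
    labels = np.linspace(0, 1, 10)
    return [
        pe.LabeledSample(
            sample_id=f"s{i}", label=float(labels[i]),
            features=np.concatenate([[labels[i]], rng.normal(size=3)]),
        )
        for i in range(10)
    ]


def pairs_of(samples):
    return pe.build_rankable_pairs(
        samples, pe.DeltaSpec(mode="absolute_difference", constant_delta=0.0)
    )


class TestLPOCV:
    def test_identity_predictor_is_perfect(self, dataset):
        verdicts, table = pe.run_lpocv(
            dataset, pairs_of(dataset), OracleAdapter(), seed=0
        )
        assert all(v.credit == 1.0 for v in verdicts)
        assert pe.estimate_auc(verdicts).auc == 1.0
        assert len(table) == len(dataset)

    def test_constant_predictor_scores_half(self, dataset):
        verdicts, _ = pe.run_lpocv(
            dataset, pairs_of(dataset), OracleAdapter(lambda x: 42.0), seed=0
        )
        assert all(v.credit == 0.5 for v in verdicts)
        assert pe.estimate_auc(verdicts).auc == 0.5

    def test_anti_predictor_scores_zero(self, dataset):
        verdicts, _ = pe.run_lpocv(
            dataset, pairs_of(dataset), OracleAdapter(lambda x: -x), seed=0
        )
        assert pe.estimate_auc(verdicts).auc == 0.0

    def test_heldout_pair_never_in_training_set(self, dataset):
        probe = LeakageProbe()
        ps = pairs_of(dataset)
        pe.run_lpocv(dataset, ps, probe, seed=0)
        label_of = {s.sample_id: s.label for s in dataset}
        assert len(probe.training_sets) == len(ps)
        for pair, train in zip(ps, probe.training_sets):
            # first feature equals the label, so identity check is exact
            assert label_of[pair.hi] not in train
            assert label_of[pair.lo] not in train
            assert len(train) == len(dataset) - 2

    def test_score_table_pools_heldout_scores(self, dataset):
        _, table = pe.run_lpocv(dataset, pairs_of(dataset), OracleAdapter(), 0)
        for s in dataset:
            assert table[s.sample_id] == pytest.approx(s.label)
            assert table.multiplicity[s.sample_id] == 9

    def test_adapter_failure_reports_fold(self, dataset):
        class Broken(OracleAdapter):
            def fit(self, X, y, seed):
                raise ValueError("boom")

        with pytest.raises(PairedEvalError, match="fold 0"):
            pe.run_lpocv(dataset, pairs_of(dataset), Broken(), seed=0)


class TestPooling:
    def test_mean_of_repeats(self):
        table = pe.pool_cv_scores([("a", 0.2), ("a", 0.4), ("b", 1.0)])
        assert table["a"] == pytest.approx(0.3)
        assert table.multiplicity == {"a": 2, "b": 1}

    def test_single_pass_unchanged(self):
        table = pe.pool_cv_scores([("a", 0.7), ("b", 0.1)])
        assert table["a"] == 0.7 and table["b"] == 0.1

    def test_empty_prediction_list_errors(self):
        with pytest.raises(CoverageError):
            pe.pool_cv_scores([])


class TestRunCV:
    def test_loo_scores_every_sample_once(self, dataset):
        table = pe.run_cv(dataset, pe.CVPlan(scheme="loo", seed=0),
                          OracleAdapter())
        assert len(table) == 10
        assert all(m == 1 for m in table.multiplicity.values())

    def test_kfold_unseen_exactly_once(self, dataset):
        table = pe.run_cv(dataset, pe.CVPlan(scheme="kfold", k=3, seed=1),
                          OracleAdapter())
        assert all(m == 1 for m in table.multiplicity.values())

    def test_monte_carlo_same_seed_identical(self, dataset):
        plan = pe.CVPlan(scheme="monte_carlo", n_repeats=20,
                         test_fraction=0.3, seed=7)
        t1 = pe.run_cv(dataset, plan, OracleAdapter())
        t2 = pe.run_cv(dataset, plan, OracleAdapter())
        assert t1.entries == t2.entries
        assert t1.multiplicity == t2.multiplicity

    def test_monte_carlo_incomplete_coverage_is_an_error(self, dataset):
        plan = pe.CVPlan(scheme="monte_carlo", n_repeats=1,
                         test_fraction=0.2, seed=7)
        with pytest.raises(CoverageError, match="never scored"):
            pe.run_cv(dataset, plan, OracleAdapter())

    def test_invalid_plans_rejected(self):
        with pytest.raises(ConfigurationError):
            pe.CVPlan(scheme="kfold", seed=0)
        with pytest.raises(ConfigurationError):
            pe.CVPlan(scheme="monte_carlo", seed=0, n_repeats=2)
        with pytest.raises(ConfigurationError):
            pe.CVPlan(scheme="warp", seed=0)

    def test_schemes_agree_on_strong_signal(self, rng):
        """LPOCV, LOO and 10-fold pooled AUC within 0.05 when noise ~ 0."""
        ds = pe.simulate_dataset(pe.SimulationParams(
            n_samples=30, n_features=10, n_signal_features=5,
            beta_signal=3.0, beta_confounder=0.0, noise_sd=0.01, seed=3,
        ))
        samples = list(ds.samples)
        spec = pe.DeltaSpec(mode="absolute_difference", constant_delta=0.2)
        ps = pe.build_rankable_pairs(samples, spec)
        adapter = pe.get_adapter("ridge")
        verdicts, _ = pe.run_lpocv(samples, ps, adapter, seed=0)
        auc_lpocv = pe.estimate_auc(verdicts).auc
        aucs = [auc_lpocv]
        for plan in (pe.CVPlan(scheme="loo", seed=0),
                     pe.CVPlan(scheme="kfold", k=10, seed=0)):
            table = pe.run_cv(samples, plan, adapter)
            aucs.append(pe.estimate_auc_bruteforce(ps, table).auc)
        assert max(aucs) - min(aucs) < 0.05


class TestImportances:
    def test_dominant_feature_ranks_first(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 5))
        y = 3.0 * X[:, 2] + rng.normal(0, 0.05, 40)
        samples = [
            pe.LabeledSample(sample_id=f"s{i}", label=float(y[i]),
                             features=X[i])
            for i in range(40)
        ]
        adapter = pe.SklearnAdapter(
            lambda seed: __import__("sklearn.ensemble", fromlist=["x"])
            .RandomForestRegressor(n_estimators=50, random_state=seed),
            feature_names=[f"g{i}" for i in range(5)],
        )
        imp = pe.fit_full_and_importances(samples, adapter, seed=0)
        assert imp.index[0] == "g2"
        assert list(imp.values) == sorted(imp.values, reverse=True)

    def test_adapter_without_importances_errors(self, dataset):
        class NoImp:
            def fit(self, X, y, seed):
                return None

            def score(self, state, X):
                return np.zeros(len(X))

            def importances(self, state):
                return None

        with pytest.raises(PairedEvalError):
            pe.fit_full_and_importances(dataset, NoImp(), seed=0)

    def test_same_seed_identical_importances(self, dataset):
        adapter = pe.get_adapter("random-forest-regressor", n_estimators=20)
        i1 = pe.fit_full_and_importances(dataset, adapter, seed=9)
        i2 = pe.fit_full_and_importances(dataset, adapter, seed=9)
        pd.testing.assert_series_equal(i1, i2)
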