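"""Cross-validation harness producing pooled out-of-sample scores.

Paired evaluation only needs per-sample prediction scores that can be pooled
across test folds, so any CV scheme works.  The natural fit is leave-pair-out
cross-validation (LPOCV): one model per rankable pair, trained on everything
except the two paired samples, which are then scored and compared head to
head.  LPOCV is less prone to stratification bias than small-fold schemes on
small datasets.  k-fold, leave-one-out and repeated Monte Carlo train/test
splits are also provided; when a sample receives several out-of-fold scores
(Monte Carlo repeats, LPOCV) the scores are averaged.

Models plug in through a small adapter contract (fit / score / optional
importances) so the harness is agnostic to the underlying learning method.
Adapters must be deterministic given (data, seed); per-fold seeds are derived
from (plan seed, fold index) so repeated runs are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Protocol, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import LogisticRegression, Ridge
from sklearn.model_selection import KFold, ShuffleSplit

from .auc import PairVerdict, ScoreTable, score_pair
from .errors import ConfigurationError, CoverageError, InputError, PairedEvalError
from .rankability import LabeledSample, RankablePairSet

__all__ = [
    "ModelAdapter",
    "SklearnAdapter",
    "CVPlan",
    "run_lpocv",
    "pool_cv_scores",
    "run_cv",
    "fit_full_and_importances",
    "get_adapter",
    "ADAPTERS",
]


class ModelAdapter(Protocol):
    """Contract every pluggable model must satisfy.

    ``fit(X, y, seed)`` returns an opaque fitted state; ``score(state, X)``
    returns one score per row, oriented so that higher = larger predicted
    label (probability of the positive class in classification);
    ``importances(state)`` optionally returns a named feature-importance
    vector, or None when the model has no such notion.
    """

    def fit(self, X: np.ndarray, y: np.ndarray, seed: int) -> object: ...

    def score(self, state: object, X: np.ndarray) -> np.ndarray: ...

    def importances(self, state: object) -> Optional[pd.Series]: ...


class SklearnAdapter:
    """Wrap a scikit-learn estimator factory as a ModelAdapter.

    ``factory(seed)`` must return an unfitted estimator.  Classifiers are
    scored by predict_proba of the largest class; regressors by predict.
    """

    def __init__(
        self,
        factory: Callable[[int], object],
        classifier: bool = False,
        feature_names: Optional[Sequence[str]] = None,
    ) -> None:
        self._factory = factory
        self._classifier = classifier
        self.feature_names = list(feature_names) if feature_names else None

    def fit(self, X: np.ndarray, y: np.ndarray, seed: int) -> object:
        est = self._factory(int(seed))
        est.fit(np.asarray(X), np.asarray(y))
        return est

    def score(self, state: object, X: np.ndarray) -> np.ndarray:
        if self._classifier:
            proba = state.predict_proba(np.asarray(X))
            return np.asarray(proba[:, -1], dtype=float)
        return np.asarray(state.predict(np.asarray(X)), dtype=float)

    def importances(self, state: object) -> Optional[pd.Series]:
        if hasattr(state, "feature_importances_"):
            vals = np.asarray(state.feature_importances_, dtype=float)
        elif hasattr(state, "coef_"):
            vals = np.abs(np.asarray(state.coef_, dtype=float)).ravel()
        else:
            return None
        names = self.feature_names or [f"f{i}" for i in range(len(vals))]
        return pd.Series(vals, index=names)


ADAPTERS: dict[str, Callable[..., SklearnAdapter]] = {
    "ridge": lambda **kw: SklearnAdapter(
        lambda seed: Ridge(**kw), classifier=False
    ),
    "logistic": lambda **kw: SklearnAdapter(
        lambda seed: LogisticRegression(max_iter=1000, **kw), classifier=True
    ),
    "random-forest-regressor": lambda **kw: SklearnAdapter(
        lambda seed: RandomForestRegressor(random_state=seed, **kw),
        classifier=False,
    ),
    "random-forest-classifier": lambda **kw: SklearnAdapter(
        lambda seed: RandomForestClassifier(random_state=seed, **kw),
        classifier=True,
    ),
}


def get_adapter(name: str, **hyperparams) -> SklearnAdapter:
    """Built-in adapter by name (see :data:`ADAPTERS`)."""
    try:
        factory = ADAPTERS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown adapter {name!r}; built-ins: {sorted(ADAPTERS)}"
        ) from None
    return factory(**hyperparams)


@dataclass(frozen=True)
class CVPlan:
    """A cross-validation scheme plus the seed that fixes its randomness."""

    scheme: str
    seed: int
    k: Optional[int] = None
    n_repeats: Optional[int] = None
    test_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        if self.scheme not in ("lpocv", "kfold", "loo", "monte_carlo"):
            raise ConfigurationError(f"unknown CV scheme {self.scheme!r}")
        if self.scheme == "kfold" and (self.k is None or self.k < 2):
            raise ConfigurationError("kfold requires k >= 2")
        if self.scheme == "monte_carlo":
            if self.n_repeats is None or self.n_repeats < 1:
                raise ConfigurationError("monte_carlo requires n_repeats >= 1")
            if not (self.test_fraction and 0 < self.test_fraction < 1):
                raise ConfigurationError(
                    "monte_carlo requires test_fraction in (0, 1)"
                )


def _fold_seed(seed: int, fold_index: int) -> int:
    """Deterministic per-fold seed below 2^31, decorrelated across folds."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(int(fold_index),))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _design(samples: Sequence[LabeledSample]) -> tuple[np.ndarray, np.ndarray, list[str]]:
    for s in samples:
        if s.features is None:
            raise InputError(f"sample {s.sample_id!r} has no feature vector")
    X = np.vstack([s.features for s in samples])
    y = np.array([float(s.label) for s in samples])
    ids = [s.sample_id for s in samples]
    return X, y, ids


def run_lpocv(
    samples: Sequence[LabeledSample],
    pairs: RankablePairSet,
    adapter: ModelAdapter,
    seed: int,
) -> tuple[list[PairVerdict], ScoreTable]:
    """Leave-pair-out CV: one model per rankable pair.

    Each model is trained on all samples except the pair's two, which are
    then scored by that model; the verdict compares the two held-out scores
    directly.  The returned ScoreTable carries, per sample, the average of
    its held-out scores across all pairs containing it.
    """
    if len(samples) < 3:
        raise InputError("LPOCV needs >= 3 samples")
    X, y, ids = _design(samples)
    index = {sid: i for i, sid in enumerate(ids)}
    missing = pairs.sample_ids() - set(ids)
    if missing:
        raise InputError(f"pairs reference unknown samples: {sorted(missing)}")

    verdicts: list[PairVerdict] = []
    predictions: list[tuple[str, float]] = []
    for fold, pair in enumerate(pairs):
        i_hi, i_lo = index[pair.hi], index[pair.lo]
        mask = np.ones(len(ids), dtype=bool)
        mask[[i_hi, i_lo]] = False
        try:
            state = adapter.fit(X[mask], y[mask], _fold_seed(seed, fold))
            s = adapter.score(state, X[[i_hi, i_lo]])
        except PairedEvalError:
            raise
        except Exception as exc:  # adapter failure: report the fold
            raise PairedEvalError(
                f"adapter failed on LPOCV fold {fold} "
                f"(pair {pair.hi!r}/{pair.lo!r}): {exc}"
            ) from exc
        if not np.all(np.isfinite(s)):
            raise InputError(
                f"non-finite score on LPOCV fold {fold} "
                f"(pair {pair.hi!r}/{pair.lo!r})"
            )
        fold_scores = ScoreTable(
            entries={pair.hi: float(s[0]), pair.lo: float(s[1])}
        )
        verdicts.append(score_pair(pair, fold_scores))
        predictions.append((pair.hi, float(s[0])))
        predictions.append((pair.lo, float(s[1])))

    return verdicts, pool_cv_scores(predictions)


def pool_cv_scores(
    per_fold_predictions: Sequence[tuple[str, float]],
) -> ScoreTable:
    """Average every sample's out-of-fold scores; record the multiplicity."""
    if len(per_fold_predictions) == 0:
        raise CoverageError("no out-of-fold predictions to pool")
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for sid, score in per_fold_predictions:
        sums[sid] = sums.get(sid, 0.0) + float(score)
        counts[sid] = counts.get(sid, 0) + 1
    entries = {sid: sums[sid] / counts[sid] for sid in sums}
    return ScoreTable(entries=entries, multiplicity=counts)


def _folds(plan: CVPlan, n: int):
    if plan.scheme == "loo":
        for i in range(n):
            test = np.array([i])
            train = np.setdiff1d(np.arange(n), test)
            yield train, test
    elif plan.scheme == "kfold":
        kf = KFold(n_splits=plan.k, shuffle=True, random_state=plan.seed)
        yield from kf.split(np.arange(n))
    elif plan.scheme == "monte_carlo":
        ss = ShuffleSplit(
            n_splits=plan.n_repeats,
            test_size=plan.test_fraction,
            random_state=plan.seed,
        )
        yield from ss.split(np.arange(n))
    else:  # pragma: no cover
        raise ConfigurationError(f"no fold iterator for scheme {plan.scheme!r}")


def run_cv(
    samples: Sequence[LabeledSample],
    plan: CVPlan,
    adapter: ModelAdapter,
    pairs: Optional[RankablePairSet] = None,
) -> ScoreTable:
    """Pooled out-of-fold scores under the plan's scheme.

    k-fold and LOO score every sample exactly once; Monte Carlo repeats are
    averaged.  ``scheme='lpocv'`` requires the rankable pair set and returns
    the pooled LPOCV scores (see :func:`run_lpocv` for the verdicts).
    """
    if plan.scheme == "lpocv":
        if pairs is None:
            raise ConfigurationError("lpocv scheme requires the pair set")
        _, table = run_lpocv(samples, pairs, adapter, plan.seed)
        return table
    X, y, ids = _design(samples)
    predictions: list[tuple[str, float]] = []
    for fold, (train, test) in enumerate(_folds(plan, len(ids))):
        if len(train) < 1:
            raise ConfigurationError(f"fold {fold} has an empty training set")
        state = adapter.fit(X[train], y[train], _fold_seed(plan.seed, fold))
        s = adapter.score(state, X[test])
        if not np.all(np.isfinite(s)):
            raise InputError(f"non-finite score in fold {fold}")
        predictions.extend(
            (ids[int(t)], float(v)) for t, v in zip(test, s)
        )
    table = pool_cv_scores(predictions)
    uncovered = [sid for sid in ids if sid not in table]
    if uncovered:
        raise CoverageError(f"samples never scored out-of-fold: {uncovered}")
    return table


def fit_full_and_importances(
    samples: Sequence[LabeledSample],
    adapter: ModelAdapter,
    seed: int,
) -> pd.Series:
    """Fit once on all samples and return importances sorted descending."""
    X, y, _ = _design(samples)
    state = adapter.fit(X, y, _fold_seed(seed, 0))
    imp = adapter.importances(state)
    if imp is None:
        raise PairedEvalError("adapter does not expose feature importances")
    return imp.sort_values(ascending=False)
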