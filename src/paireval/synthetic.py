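"""Synthetic datasets with the structure paired evaluation targets.

The generator emulates small-sample expression-like studies: tens of samples,
hundreds to thousands of Gaussian features, a continuous label driven by a
small block of signal features, and a confounder that shifts both a feature
block and the label — the situation in which a model can score well by
learning the confounder instead of the signal.  Optional extras: technical
replicates (yielding per-sample label SDs for replicate-based rankability
thresholds) and injected outliers whose label is moved to the opposite tail
while their features are left untouched, mimicking a sample whose molecular
profile clusters with one group while its measured response resembles the
other.

Features are plain Gaussians: the aim is to exercise the evaluation
machinery, not to mimic RNA-seq count distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .auc import ScoreTable
from .errors import InputError
from .rankability import LabeledSample

__all__ = ["SimulationParams", "SyntheticDataset", "simulate_dataset",
           "make_toy_fixture"]


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the generator; defaults give a confounded regression study.

    ``beta_signal`` / ``beta_confounder`` are the label effects of the mean
    signal feature and of the (0/1 or standardized continuous) confounder;
    ``confounder_feature_shift`` is the mean shift the confounder imprints
    on its own feature block, so the confounder is visible to the model.
    ``n_outliers`` samples get their label replaced by a draw from the
    opposite tail of the label distribution; ``outlier_mode='features'``
    instead perturbs the feature vector and leaves the label alone.
    """

    n_samples: int = 60
    n_features: int = 100
    n_signal_features: int = 10
    beta_signal: float = 1.0
    beta_confounder: float = 1.0
    confounder_kind: str = "binary"  # binary | continuous_censored
    confounder_feature_shift: float = 1.0
    noise_sd: float = 0.3
    n_replicates: int = 3
    replicate_sd: float = 0.2
    n_outliers: int = 0
    outlier_mode: str = "label"  # label | features
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_samples, self.n_features) < 1:
            raise InputError("n_samples and n_features must be >= 1")
        if not 0 <= self.n_signal_features <= self.n_features:
            raise InputError("n_signal_features must be in [0, n_features]")
        if self.noise_sd < 0 or self.replicate_sd < 0:
            raise InputError("standard deviations must be >= 0")
        if self.n_outliers < 0 or self.n_outliers > self.n_samples:
            raise InputError("n_outliers must be in [0, n_samples]")
        if self.confounder_kind not in ("binary", "continuous_censored"):
            raise InputError(f"unknown confounder_kind {self.confounder_kind!r}")
        if self.outlier_mode not in ("label", "features"):
            raise InputError(f"unknown outlier_mode {self.outlier_mode!r}")
        if self.n_replicates < 2:
            raise InputError("n_replicates must be >= 2 to estimate an SD")


@dataclass(frozen=True)
class SyntheticDataset:
    """Samples plus ground truth: which samples were injected as outliers."""

    samples: tuple[LabeledSample, ...]
    outlier_ids: frozenset[str]
    params: SimulationParams = field(repr=False, default=None)  # type: ignore[assignment]


# censoring convention mirrors age-of-death annotations: uniform 65-95,
# reported values clipped at 90
_AGE_LO, _AGE_HI, _AGE_CENSOR = 65.0, 95.0, 90.0


def simulate_dataset(params: SimulationParams) -> SyntheticDataset:
    """Draw one dataset; fully reproducible from ``params.seed``.

    label_i = beta_signal * mean(signal features_i)
              + beta_confounder * c_i + N(0, noise_sd)

    where c_i is the binary confounder or the standardized (uncensored)
    continuous one.  The confounder also shifts a dedicated feature block by
    ``confounder_feature_shift * c_i``.  Replicate SDs are the sample SD of
    ``n_replicates`` label re-draws at ``replicate_sd`` noise.  Outliers are
    injected last and alter only the flagged samples.
    """
    rng = np.random.default_rng(params.seed)
    n, p = params.n_samples, params.n_features
    ids = [f"S{i:03d}" for i in range(n)]

    if params.confounder_kind == "binary":
        conf_raw = rng.integers(0, 2, size=n).astype(float)
        conf_effect = conf_raw
        conf_out = conf_raw
    else:
        age = rng.uniform(_AGE_LO, _AGE_HI, size=n)
        conf_effect = (age - age.mean()) / age.std()
        conf_out = np.minimum(age, _AGE_CENSOR)
        conf_raw = age

    X = rng.standard_normal((n, p))
    k = params.n_signal_features
    # confounder imprints on its own feature block, disjoint from the signal
    block = slice(k, min(2 * k, p)) if k > 0 else slice(0, min(10, p))
    X[:, block] += params.confounder_feature_shift * conf_effect[:, None]

    signal = X[:, :k].mean(axis=1) if k > 0 else np.zeros(n)
    labels = (
        params.beta_signal * signal
        + params.beta_confounder * conf_effect
        + rng.normal(0.0, params.noise_sd, size=n)
    )

    reps = labels[:, None] + rng.normal(
        0.0, params.replicate_sd, size=(n, params.n_replicates)
    )
    rep_sd = reps.std(axis=1, ddof=1)

    # injection targets come from the outer label quartiles: an opposite-tail
    # flip is only meaningful for a sample that sits toward one side, like a
    # cell line whose molecular profile clusters with one response group
    # while its measured response resembles the other
    q25, q75 = np.quantile(labels, [0.25, 0.75])
    eligible = np.flatnonzero((labels <= q25) | (labels >= q75))
    if params.n_outliers > eligible.size:
        raise InputError("n_outliers exceeds the number of tail samples")
    outlier_idx = rng.choice(eligible, size=params.n_outliers, replace=False)
    median = float(np.median(labels))
    lo_tail = (float(labels.min()), float(np.quantile(labels, 0.1)))
    hi_tail = (float(np.quantile(labels, 0.9)), float(labels.max()))
    for i in outlier_idx:
        if params.outlier_mode == "label":
            tail = lo_tail if labels[i] > median else hi_tail
            labels[i] = float(rng.uniform(*tail))
        else:
            X[i] = rng.standard_normal(p) * 3.0

    samples = tuple(
        LabeledSample(
            sample_id=ids[i],
            label=float(labels[i]),
            features=X[i].copy(),
            replicate_sd=float(rep_sd[i]),
            confounders={"confounder": float(conf_out[i])},
        )
        for i in range(n)
    )
    return SyntheticDataset(
        samples=samples,
        outlier_ids=frozenset(ids[int(i)] for i in outlier_idx),
        params=params,
    )


def make_toy_fixture() -> tuple[list[LabeledSample], ScoreTable, float]:
    """A fixed 8-sample binary dataset with hand-enumerable pairs.

    Labels: four negatives (A-D) and four positives (E-H), so the 16
    cross-class pairs are exactly the rankable set.  Scores are fixed and
    tie-free; enumerating the 16 pairs by hand gives 11 correctly ranked,
    hence AUC = 11/16 = 0.6875 (frozen here and asserted in tests).
    """
    labels = [0, 0, 0, 0, 1, 1, 1, 1]
    scores = [0.10, 0.40, 0.35, 0.80, 0.70, 0.20, 0.90, 0.60]
    ids = list("ABCDEFGH")
    samples = [
        LabeledSample(
            sample_id=i,
            label=float(y),
            features=np.array([float(y), s]),
        )
        for i, y, s in zip(ids, labels, scores)
    ]
    table = ScoreTable(entries=dict(zip(ids, map(float, scores))))
    return samples, table, 11.0 / 16.0
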