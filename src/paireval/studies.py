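"""Canonical simulation studies exercising the evaluation diagnostics.

Two self-contained studies, each run over many seeds:

* **Confounder recovery** — labels driven purely by a binary confounder
  (no signal): the matched-pair AUC should collapse relative to the
  all-pairs AUC with a significant one-sided Fisher test.  The clean
  control (no confounder effect on the label) should show no gap.
* **Outlier recovery** — one tail sample's label is flipped to the opposite
  tail: the outlier scan should rank that sample first by adjusted p.

Study conditions are fixed here, once, as part of the study design:
small-sample expression-like data (n = 60 / 40 samples), ridge models,
rankability threshold delta = 0.3 on labels of roughly unit scale (the
scale of replicate-level measurement error the generator emulates).  The
confounder study pools leave-one-out scores — any pooled-CV scheme is
valid for paired evaluation and LOO keeps the 50-seed study cheap; the
outlier study uses LPOCV, whose per-pair models make per-sample misranking
patterns sharpest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .auc import estimate_auc, score_pairs
from .confounders import ConfounderSpec, confounder_effect, split_pairs_discrete
from .cv import CVPlan, get_adapter, run_cv, run_lpocv
from .outliers import outlier_scan
from .rankability import DeltaSpec, build_rankable_pairs
from .synthetic import SimulationParams, simulate_dataset

__all__ = [
    "ConfounderStudyResult",
    "OutlierStudyResult",
    "run_confounder_study",
    "run_outlier_study",
]

_DELTA = DeltaSpec(mode="absolute_difference", constant_delta=0.3)


@dataclass(frozen=True)
class ConfounderStudyResult:
    delta_aucs: tuple[float, ...]
    p_values: tuple[float, ...]

    @property
    def median_delta_auc(self) -> float:
        return float(np.median(self.delta_aucs))

    @property
    def median_abs_delta_auc(self) -> float:
        return float(np.median(np.abs(self.delta_aucs)))

    def significant_fraction(self, alpha: float = 0.01) -> float:
        return float(np.mean(np.asarray(self.p_values) < alpha))


@dataclass(frozen=True)
class OutlierStudyResult:
    hits: tuple[bool, ...]
    overall_aucs: tuple[float, ...]

    @property
    def top_rank_fraction(self) -> float:
        return float(np.mean(self.hits))


def _confounder_seed_run(seed: int, beta_signal: float, beta_confounder: float):
    params = SimulationParams(
        n_samples=60,
        beta_signal=beta_signal,
        beta_confounder=beta_confounder,
        confounder_kind="binary",
        seed=seed,
    )
    ds = simulate_dataset(params)
    samples = list(ds.samples)
    pairs = build_rankable_pairs(samples, _DELTA)
    table = run_cv(samples, CVPlan(scheme="loo", seed=seed), get_adapter("ridge"))
    verdicts = score_pairs(pairs, table)
    spec = ConfounderSpec(name="confounder", kind="discrete")
    matched, mismatched = split_pairs_discrete(pairs, samples, spec)
    return confounder_effect(verdicts, matched, mismatched)


def run_confounder_study(
    n_seeds: int = 50,
    base_seed: int = 0,
    confounded: bool = True,
) -> ConfounderStudyResult:
    """Confounder-effect recovery over ``n_seeds`` simulated datasets.

    ``confounded=True``: the label is driven only by the confounder
    (beta_signal = 0, beta_confounder = 1).  ``confounded=False`` is the
    clean control (beta_signal = 1, beta_confounder = 0).
    """
    beta_signal, beta_confounder = (0.0, 1.0) if confounded else (1.0, 0.0)
    deltas, ps = [], []
    for i in range(n_seeds):
        eff = _confounder_seed_run(base_seed + i, beta_signal, beta_confounder)
        deltas.append(eff.delta_auc)
        ps.append(eff.p_value)
    return ConfounderStudyResult(delta_aucs=tuple(deltas), p_values=tuple(ps))


def run_outlier_study(n_seeds: int = 50, base_seed: int = 0) -> OutlierStudyResult:
    """Outlier recovery: is the injected flip the top-ranked scan hit?

    n = 40 samples, 40 features, strong signal (beta_signal = 2, label
    noise 0.1), one label-flipped tail sample; ridge LPOCV verdicts.
    """
    hits, aucs = [], []
    for i in range(n_seeds):
        seed = base_seed + i
        params = SimulationParams(
            n_samples=40,
            n_features=40,
            n_signal_features=10,
            beta_signal=2.0,
            beta_confounder=0.0,
            noise_sd=0.1,
            n_outliers=1,
            seed=seed,
        )
        ds = simulate_dataset(params)
        samples = list(ds.samples)
        pairs = build_rankable_pairs(samples, _DELTA)
        verdicts, _ = run_lpocv(samples, pairs, get_adapter("ridge"), seed)
        reports = outlier_scan(verdicts)
        top = min(reports, key=lambda r: (r.p_adjusted, r.p_value))
        hits.append(top.sample_id in ds.outlier_ids)
        aucs.append(estimate_auc(verdicts).auc)
    return OutlierStudyResult(hits=tuple(hits), overall_aucs=tuple(aucs))
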