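"""Outlier detection from per-sample ranking performance.

For each sample k, the sample-specific AUC restricts the paired-evaluation
tally to R_k, the rankable pairs containing k::

    AUC_k = sum_{(i,j) in R_k} p_ij / |R_k|

A sample whose pairs are disproportionately misranked — relative to the
pairs that do not contain it — is a candidate outlier: its label may be
erroneous, or the sample may be biologically unlike the rest of the dataset.
Enrichment of misranking in R_k is assessed with a one-sided Fisher's exact
test (alternative: pairs containing k are more likely misranked), with
Benjamini-Hochberg correction across the scanned samples.

Detection is advisory: :func:`remove_and_reevaluate` quantifies the effect
of dropping a sample (rebuilding pairs and retraining), but the decision to
remove is the analyst's.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd
from statsmodels.stats.multitest import multipletests

from .auc import AUCEstimate, PairVerdict, estimate_auc
from .compare import ContingencyTable2x2, fisher_exact
from .cv import ModelAdapter, fit_full_and_importances, run_lpocv
from .errors import InputError, UndefinedAUCError
from .rankability import DeltaSpec, LabeledSample, build_rankable_pairs

__all__ = ["OutlierReport", "RemovalResult", "sample_auc", "outlier_scan",
           "remove_and_reevaluate"]


@dataclass(frozen=True)
class OutlierReport:
    """Per-sample scan result: AUC_k, its enrichment table and Fisher p."""

    sample_id: str
    n_pairs_k: int
    credit_k: float
    auc_k: float
    table: ContingencyTable2x2
    p_value: float
    p_adjusted: float


@dataclass(frozen=True)
class RemovalResult:
    before: AUCEstimate
    after: AUCEstimate
    importances_before: Optional[pd.Series] = None
    importances_after: Optional[pd.Series] = None


def sample_auc(verdicts: Sequence[PairVerdict], k: str) -> AUCEstimate:
    """AUC over the subset of verdicts whose pair contains sample k."""
    sub = [v for v in verdicts if v.pair.contains(k)]
    if not sub:
        raise UndefinedAUCError(f"sample {k!r} appears in no rankable pair")
    return estimate_auc(sub)


def _tally(verdicts: Sequence[PairVerdict]) -> tuple[int, int]:
    """(correct, incorrect) integer tallies; half credits count as incorrect."""
    correct = sum(1 for v in verdicts if v.credit == 1.0)
    return correct, len(verdicts) - correct


def outlier_scan(
    verdicts: Sequence[PairVerdict],
    samples: Optional[Sequence[str]] = None,
) -> list[OutlierReport]:
    """Scan every sample for misranking enrichment among its pairs.

    Returns one report per scanned sample, sorted by ascending raw p.  The
    Fisher table contrasts in-R_k against not-in-R_k correct/incorrect
    counts, one-sided with the alternative that pairs containing the sample
    are more likely misranked.  ``p_adjusted`` is Benjamini-Hochberg across
    the scan.
    """
    if not verdicts:
        raise InputError("empty verdict list")
    if samples is None:
        ids = sorted({s for v in verdicts for s in (v.pair.hi, v.pair.lo)})
    else:
        ids = list(samples)

    reports = []
    for k in ids:
        in_k = [v for v in verdicts if v.pair.contains(k)]
        if not in_k:
            continue
        out_k = [v for v in verdicts if not v.pair.contains(k)]
        c_in, i_in = _tally(in_k)
        c_out, i_out = _tally(out_k)
        table = ContingencyTable2x2(
            a=c_in, b=i_in, c=c_out, d=i_out,
            row_labels=(f"pairs with {k}", f"pairs without {k}"),
            col_labels=("correct", "incorrect"),
        )
        # misranking enrichment in R_k == depletion of the correct cell
        res = fisher_exact(table, alternative="less")
        est = estimate_auc(in_k)
        reports.append(
            (k, len(in_k), est.credit_sum, est.auc, table, res.p_value)
        )

    if len(reports) < 2:
        raise InputError("need >= 2 samples with non-empty R_k to scan")
    raw = [r[5] for r in reports]
    _, adjusted, _, _ = multipletests(raw, method="fdr_bh")
    out = [
        OutlierReport(
            sample_id=k, n_pairs_k=n, credit_k=c, auc_k=a, table=t,
            p_value=p, p_adjusted=float(q),
        )
        for (k, n, c, a, t, p), q in zip(reports, adjusted)
    ]
    out.sort(key=lambda r: (r.p_value, r.sample_id))
    return out


def remove_and_reevaluate(
    samples: Sequence[LabeledSample],
    exclude: str,
    spec: DeltaSpec,
    adapter: ModelAdapter,
    seed: int,
    with_importances: bool = False,
) -> RemovalResult:
    """AUC before and after excluding one sample, retraining all models.

    Pairs are rebuilt without the excluded sample (so the pair count drops
    by exactly |R_k|) and LPOCV is rerun from scratch.  Optionally also
    returns full-fit feature importances before/after for interpretation.
    """
    ids = [s.sample_id for s in samples]
    if exclude not in ids:
        raise InputError(f"sample {exclude!r} not in dataset")
    kept = [s for s in samples if s.sample_id != exclude]
    if len(kept) < 3:
        raise InputError("exclusion leaves fewer than 3 samples")

    pairs_before = build_rankable_pairs(samples, spec)
    pairs_after = build_rankable_pairs(kept, spec)
    if len(pairs_after) < 1:
        raise InputError("exclusion leaves no rankable pairs")

    verd_before, _ = run_lpocv(samples, pairs_before, adapter, seed)
    verd_after, _ = run_lpocv(kept, pairs_after, adapter, seed)

    imp_b = imp_a = None
    if with_importances:
        imp_b = fit_full_and_importances(samples, adapter, seed)
        imp_a = fit_full_and_importances(kept, adapter, seed)
    return RemovalResult(
        before=estimate_auc(verd_before),
        after=estimate_auc(verd_after),
        importances_before=imp_b,
        importances_after=imp_a,
    )
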