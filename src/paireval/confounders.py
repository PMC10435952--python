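"""Confounder-matched evaluation.

A predictor can earn a high pairwise AUC simply by recognizing a variable
that co-varies with the label (tumor subtype, age, collection site).  To
detect this without modifying the data, rankable pairs are partitioned into
*confounder-matched* pairs — both samples share (or nearly share) the
confounder value, so correct ranking cannot come from recognizing it — and
*mismatched* pairs.  A matched-pair AUC substantially below the all-pairs
AUC, with a significant one-sided Fisher test, indicates the model has at
least partially learned the confounder.

Discrete confounders are matched exactly.  Continuous confounders (possibly
censored at a bound, e.g. age of death censored at 90) are handled by
selecting, per index sample, one rankable partner minimizing the confounder
difference (matched) and one maximizing it or drawn at random from the
censored category (mismatched) — giving each data point its minimal- and
maximal-separation pair along the confounding variable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .auc import AUCEstimate, PairVerdict, estimate_auc
from .compare import ContingencyTable2x2, fisher_exact
from .errors import ConfigurationError, InputError, UndefinedAUCError
from .rankability import LabeledSample, RankablePair, RankablePairSet

logger = logging.getLogger(__name__)

__all__ = [
    "ConfounderSpec",
    "ConfounderEffect",
    "split_pairs_discrete",
    "select_pairs_continuous",
    "confounder_effect",
    "anova_f",
]


@dataclass(frozen=True)
class ConfounderSpec:
    """Which confounder to control and how pairs are matched on it."""

    name: str
    kind: str  # discrete | continuous
    censor_at: Optional[float] = None
    matched_strategy: str = "exact"
    mismatched_strategy: str = "all_remaining"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in ("discrete", "continuous"):
            raise ConfigurationError(f"unknown confounder kind {self.kind!r}")
        if self.kind == "discrete" and self.matched_strategy != "exact":
            raise ConfigurationError("discrete confounders match exactly")
        if self.kind == "continuous" and self.matched_strategy != "min_difference":
            raise ConfigurationError(
                "continuous confounders require matched_strategy="
                "'min_difference'"
            )
        if self.mismatched_strategy not in (
            "all_remaining", "max_difference", "random_from_censored"
        ):
            raise ConfigurationError(
                f"unknown mismatched_strategy {self.mismatched_strategy!r}"
            )
        if self.mismatched_strategy == "random_from_censored" and self.seed is None:
            raise ConfigurationError(
                "random_from_censored requires a seed"
            )


@dataclass(frozen=True)
class ConfounderEffect:
    """All/matched/mismatched AUCs plus the exact-test contrast."""

    auc_all: AUCEstimate
    auc_matched: AUCEstimate
    auc_mismatched: AUCEstimate
    table: ContingencyTable2x2
    p_value: float

    @property
    def delta_auc(self) -> float:
        return self.auc_all.auc - self.auc_matched.auc


def _confounder_values(
    samples: Sequence[LabeledSample], spec: ConfounderSpec
) -> dict[str, object]:
    vals: dict[str, object] = {}
    missing = []
    for s in samples:
        if spec.name not in s.confounders:
            missing.append(s.sample_id)
        else:
            vals[s.sample_id] = s.confounders[spec.name]
    if missing:
        raise InputError(
            f"samples missing confounder {spec.name!r}: {missing}"
        )
    return vals


def split_pairs_discrete(
    pairs: RankablePairSet,
    samples: Sequence[LabeledSample],
    spec: ConfounderSpec,
) -> tuple[RankablePairSet, RankablePairSet]:
    """Partition pairs into confounder-matched (equal values) and the rest."""
    if spec.kind != "discrete":
        raise ConfigurationError("split_pairs_discrete needs a discrete spec")
    vals = _confounder_values(samples, spec)
    matched, mismatched = [], []
    for p in pairs:
        (matched if vals[p.hi] == vals[p.lo] else mismatched).append(p)
    return (
        RankablePairSet(pairs=tuple(matched), n_samples=pairs.n_samples),
        RankablePairSet(pairs=tuple(mismatched), n_samples=pairs.n_samples),
    )


def _is_censored(value: float, spec: ConfounderSpec) -> bool:
    return spec.censor_at is not None and float(value) >= spec.censor_at


def _gap(v1: float, v2: float, spec: ConfounderSpec) -> float:
    """Effective confounder separation; two censored values are one category."""
    if _is_censored(v1, spec) and _is_censored(v2, spec):
        return 0.0
    c1 = min(float(v1), spec.censor_at) if spec.censor_at is not None else float(v1)
    c2 = min(float(v2), spec.censor_at) if spec.censor_at is not None else float(v2)
    return abs(c1 - c2)


def select_pairs_continuous(
    pairs: RankablePairSet,
    samples: Sequence[LabeledSample],
    spec: ConfounderSpec,
) -> tuple[RankablePairSet, RankablePairSet]:
    """One matched and one mismatched pair per index sample.

    Matched: the rankable partner minimizing the confounder gap (two
    censored values count as gap 0); ties broken by smallest partner id.
    Mismatched per ``spec.mismatched_strategy``: the maximal-gap partner, a
    random partner from the censored category (drawn without replacement
    across index samples while candidates remain, seeded), or all remaining
    pairs.  Index samples whose matched and mismatched choices coincide
    contribute only the matched pair.
    """
    if spec.kind != "continuous":
        raise ConfigurationError("select_pairs_continuous needs a continuous spec")
    vals = {k: float(v) for k, v in _confounder_values(samples, spec).items()}

    partners: dict[str, list[str]] = {}
    pair_by_key: dict[frozenset, RankablePair] = {}
    for p in pairs:
        partners.setdefault(p.hi, []).append(p.lo)
        partners.setdefault(p.lo, []).append(p.hi)
        pair_by_key[frozenset((p.hi, p.lo))] = p

    rng = np.random.default_rng(spec.seed)
    matched_keys: list[frozenset] = []
    mismatched_keys: list[frozenset] = []
    used_censored: set[frozenset] = set()

    for idx in sorted(partners):
        cand = sorted(partners[idx])
        if not cand:
            logger.warning("sample %s has no rankable partner; skipped", idx)
            continue
        m = min(cand, key=lambda c: (_gap(vals[idx], vals[c], spec), c))
        m_key = frozenset((idx, m))
        matched_keys.append(m_key)

        if spec.mismatched_strategy == "all_remaining":
            for c in cand:
                key = frozenset((idx, c))
                if key != m_key:
                    mismatched_keys.append(key)
            continue
        if spec.mismatched_strategy == "max_difference":
            best = max(_gap(vals[idx], vals[c], spec) for c in cand)
            # deterministic tie-break: smallest id among maximal gaps
            mm = min(c for c in cand if _gap(vals[idx], vals[c], spec) == best)
            mm_key = frozenset((idx, mm))
        else:  # random_from_censored
            cens = [c for c in cand if _is_censored(vals[c], spec)]
            if not cens:
                logger.warning(
                    "sample %s has no censored rankable partner; skipped", idx
                )
                continue
            fresh = [c for c in cens if frozenset((idx, c)) not in used_censored]
            pool = fresh if fresh else cens
            mm = pool[int(rng.integers(len(pool)))]
            mm_key = frozenset((idx, mm))
            used_censored.add(mm_key)
        if mm_key != m_key:
            mismatched_keys.append(mm_key)

    def _dedupe(keys: list[frozenset]) -> tuple[RankablePair, ...]:
        seen, out = set(), []
        for k in keys:
            if k not in seen:
                seen.add(k)
                out.append(pair_by_key[k])
        out.sort(key=lambda p: (p.hi, p.lo))
        return tuple(out)

    return (
        RankablePairSet(pairs=_dedupe(matched_keys), n_samples=pairs.n_samples),
        RankablePairSet(pairs=_dedupe(mismatched_keys), n_samples=pairs.n_samples),
    )


def confounder_effect(
    verdicts: Sequence[PairVerdict],
    matched: RankablePairSet,
    mismatched: RankablePairSet,
) -> ConfounderEffect:
    """Contrast matched vs mismatched correctness with a one-sided Fisher test.

    The table rows are the disjoint matched / mismatched sets; the
    alternative is that matched pairs are more likely misranked.  A small p
    together with a positive delta_auc indicates the predictor learned the
    confounder.  ``auc_all`` is computed over all supplied verdicts.
    """
    if len(matched) == 0 or len(mismatched) == 0:
        raise UndefinedAUCError(
            "confounder effect undefined with an empty matched or "
            "mismatched set"
        )
    by_key = {v.pair.key: v for v in verdicts}

    def _subset(ps: RankablePairSet) -> list[PairVerdict]:
        out = []
        missing = []
        for p in ps:
            v = by_key.get(p.key)
            if v is None:
                missing.append(p.key)
            else:
                out.append(v)
        if missing:
            raise InputError(f"verdicts missing for pairs: {missing[:5]}")
        return out

    vm = _subset(matched)
    vmm = _subset(mismatched)

    def _tally(vs: Sequence[PairVerdict]) -> tuple[int, int]:
        c = sum(1 for v in vs if v.credit == 1.0)
        return c, len(vs) - c

    cm, im = _tally(vm)
    cmm, imm = _tally(vmm)
    table = ContingencyTable2x2(
        a=cm, b=im, c=cmm, d=imm,
        row_labels=("matched", "mismatched"),
        col_labels=("correct", "incorrect"),
    )
    # matched more likely misranked == correct cell depleted in row 1
    res = fisher_exact(table, alternative="less")
    return ConfounderEffect(
        auc_all=estimate_auc(list(verdicts)),
        auc_matched=estimate_auc(vm),
        auc_mismatched=estimate_auc(vmm),
        table=table,
        p_value=res.p_value,
    )


def anova_f(
    labels: Sequence[float], groups: Sequence[object]
) -> tuple[float, float]:
    """One-way ANOVA of the label across confounder groups.

    Returns (F, p) with df (g - 1, N - g).  A large F indicates the label
    distribution differs across confounder values — the setting in which a
    predictor is most likely to pick up the confounder.
    """
    labels = np.asarray(labels, dtype=float)
    groups = np.asarray(groups)
    if labels.shape[0] != groups.shape[0]:
        raise InputError("labels and groups must have equal length")
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise InputError("need >= 2 groups")
    arrays = [labels[groups == g] for g in uniq]
    for g, arr in zip(uniq, arrays):
        if arr.size < 2:
            raise InputError(f"group {g!r} has fewer than 2 members")
    f, p = stats.f_oneway(*arrays)
    return float(f), float(p)
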