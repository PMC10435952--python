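"""Rankable-pair construction.

A pair of samples (i, j) is *rankable* when the separation of their labels
exceeds a minimum threshold delta::

    f(y_i, y_j) >= delta_ij

where ``f`` is an indicator on label inequality for classification / ordinal
tasks, or the absolute label difference for regression tasks.  For regression,
``delta_ij`` is typically taken as ``max(sigma_i, sigma_j)``, the larger of the
two samples' technical-replicate standard deviations: a model is not asked to
order two samples whose labels are indistinguishable given measurement error.

The set R of rankable pairs is the denominator of the paired-evaluation AUC
(see :mod:`paireval.auc`).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import numpy as np

from .errors import ConfigurationError, InputError

logger = logging.getLogger(__name__)

__all__ = [
    "LabeledSample",
    "DeltaSpec",
    "RankablePair",
    "RankablePairSet",
    "pair_delta",
    "is_rankable",
    "build_rankable_pairs",
    "default_delta_spec",
]


@dataclass(frozen=True)
class LabeledSample:
    """One data point: id, label, and optional features / replicate SD / confounders.

    ``label`` is numeric; ordinal categories must be mapped to integers with the
    declared total order before construction.  ``replicate_sd`` is the standard
    deviation of the label across technical replicates (sigma_i), used for
    replicate-based rankability thresholds.
    """

    sample_id: str
    label: float
    features: Optional[np.ndarray] = None
    replicate_sd: Optional[float] = None
    confounders: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.replicate_sd is not None and self.replicate_sd < 0:
            raise InputError(
                f"replicate_sd must be >= 0 for sample {self.sample_id!r}, "
                f"got {self.replicate_sd}"
            )
        if self.features is not None:
            object.__setattr__(
                self, "features", np.asarray(self.features, dtype=float)
            )


@dataclass(frozen=True)
class DeltaSpec:
    """How the rankability threshold delta_ij is chosen for each pair.

    ``indicator`` mode: f is an indicator on label inequality and delta is
    fixed at 0.5, so a pair is rankable iff the labels differ (classification,
    ordinal stages).  ``absolute_difference`` mode: f = |y_i - y_j| and delta
    is either a constant or max(sigma_i, sigma_j) from technical replicates.
    """

    mode: str = "indicator"
    constant_delta: Optional[float] = None
    use_replicate_sd: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("indicator", "absolute_difference"):
            raise ConfigurationError(f"unknown delta mode {self.mode!r}")
        if self.mode == "absolute_difference":
            if (self.constant_delta is None) == (not self.use_replicate_sd):
                raise ConfigurationError(
                    "absolute_difference mode requires exactly one of "
                    "constant_delta / use_replicate_sd"
                )
            if self.constant_delta is not None and self.constant_delta < 0:
                raise ConfigurationError("constant_delta must be >= 0")
        else:
            if self.constant_delta is not None or self.use_replicate_sd:
                raise ConfigurationError(
                    "indicator mode takes neither constant_delta nor "
                    "use_replicate_sd"
                )


@dataclass(frozen=True)
class RankablePair:
    """An oriented rankable pair: ``hi`` has the strictly larger label."""

    hi: str
    lo: str
    delta_used: float

    def __post_init__(self) -> None:
        if self.hi == self.lo:
            raise InputError(f"degenerate pair ({self.hi!r}, {self.hi!r})")

    @property
    def key(self) -> tuple[str, str]:
        return (self.hi, self.lo)

    def contains(self, sample_id: str) -> bool:
        return sample_id == self.hi or sample_id == self.lo


@dataclass(frozen=True)
class RankablePairSet:
    """The set R of rankable pairs over a dataset of ``n_samples`` samples."""

    pairs: tuple[RankablePair, ...]
    n_samples: int

    def __post_init__(self) -> None:
        seen = set()
        for p in self.pairs:
            k = frozenset((p.hi, p.lo))
            if k in seen:
                raise InputError(f"duplicate unordered pair {sorted(k)}")
            seen.add(k)
        max_pairs = self.n_samples * (self.n_samples - 1) // 2
        if len(self.pairs) > max_pairs:
            raise InputError(
                f"{len(self.pairs)} pairs exceed C({self.n_samples}, 2)"
            )

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self) -> Iterator[RankablePair]:
        return iter(self.pairs)

    def sample_ids(self) -> set[str]:
        out: set[str] = set()
        for p in self.pairs:
            out.add(p.hi)
            out.add(p.lo)
        return out

    def pairs_containing(self, sample_id: str) -> "RankablePairSet":
        """The subset R_k of pairs that include ``sample_id``."""
        sub = tuple(p for p in self.pairs if p.contains(sample_id))
        return RankablePairSet(pairs=sub, n_samples=self.n_samples)

    def without_sample(self, sample_id: str) -> "RankablePairSet":
        sub = tuple(p for p in self.pairs if not p.contains(sample_id))
        return RankablePairSet(pairs=sub, n_samples=max(self.n_samples - 1, 0))


def pair_delta(a: LabeledSample, b: LabeledSample, spec: DeltaSpec) -> float:
    """The rankability threshold delta for the pair (a, b) under ``spec``."""
    if spec.mode == "indicator":
        return 0.5
    if spec.use_replicate_sd:
        for s in (a, b):
            if s.replicate_sd is None:
                raise ConfigurationError(
                    f"replicate-SD delta requested but sample "
                    f"{s.sample_id!r} has no replicate_sd"
                )
        return max(a.replicate_sd, b.replicate_sd)  # type: ignore[type-var]
    assert spec.constant_delta is not None
    return spec.constant_delta


def is_rankable(a: LabeledSample, b: LabeledSample, spec: DeltaSpec) -> bool:
    """Whether the labels of ``a`` and ``b`` are separated by at least delta.

    Identical labels are never rankable: there is no ordering to recover.
    """
    ya, yb = float(a.label), float(b.label)
    if ya == yb:
        return False
    if spec.mode == "indicator":
        return True
    return abs(ya - yb) >= pair_delta(a, b, spec)


def build_rankable_pairs(
    samples: Sequence[LabeledSample], spec: Optional[DeltaSpec] = None
) -> RankablePairSet:
    """Construct R: every unordered sample pair passing :func:`is_rankable`.

    Pairs are oriented (``hi`` = larger label) and returned sorted by
    (hi, lo) sample id so the output is deterministic.
    """
    if len(samples) < 2:
        raise InputError(f"need >= 2 samples, got {len(samples)}")
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise InputError("duplicate sample_id in dataset")
    if spec is None:
        spec = default_delta_spec(samples)
    out = []
    for a, b in itertools.combinations(samples, 2):
        if not is_rankable(a, b, spec):
            continue
        hi, lo = (a, b) if a.label > b.label else (b, a)
        out.append(
            RankablePair(
                hi=hi.sample_id, lo=lo.sample_id,
                delta_used=pair_delta(a, b, spec),
            )
        )
    if not out:
        logger.warning(
            "no rankable pairs among %d samples; downstream AUC is undefined",
            len(samples),
        )
    out.sort(key=lambda p: (p.hi, p.lo))
    return RankablePairSet(pairs=tuple(out), n_samples=len(samples))


def default_delta_spec(samples: Sequence[LabeledSample]) -> DeltaSpec:
    """Fallback when no DeltaSpec is given.

    Few distinct label values (<= 10) look like classes / ordinal stages:
    indicator mode.  Otherwise treat the task as regression with a zero
    threshold, i.e. any strict label difference is rankable.  Either way the
    choice is logged loudly; callers with replicate SDs or domain knowledge
    should pass an explicit spec.
    """
    distinct = len({float(s.label) for s in samples})
    if distinct <= 10:
        spec = DeltaSpec(mode="indicator")
    else:
        spec = DeltaSpec(mode="absolute_difference", constant_delta=0.0)
    logger.warning(
        "no DeltaSpec given: defaulting to %s mode based on %d distinct "
        "label values", spec.mode, distinct,
    )
    return spec
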