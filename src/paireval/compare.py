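"""Model comparison via exact contingency-table tests.

Two models evaluated on the same rankable pairs are compared in two ways:

* a *marginal* 2x2 table (model x correct/incorrect) tested with Fisher's
  exact test — sensitive to a difference in the overall fraction of
  correctly ranked pairs;
* a *paired* 2x2 table (both correct / only A / only B / both incorrect)
  whose discordant cells feed an exact McNemar test — able to detect that
  two models disagree pair-by-pair even when their AUCs are similar.

Both tests are exact (hypergeometric / binomial), matching the small-sample
regime the framework targets.  Half-credit (tied-score) verdicts are counted
as incorrect for both models by default, since exact tests need integer
tallies; pass ``tie_policy='exclude'`` to drop tied pairs instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .auc import PairVerdict
from .errors import AlignmentError, InputError

__all__ = [
    "ContingencyTable2x2",
    "TestResult",
    "build_comparison_tables",
    "fisher_exact",
    "mcnemar",
    "compare_correctness_tallies",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Labeled 2x2 counts: [[a, b], [c, d]] with row/column descriptions."""

    a: int
    b: int
    c: int
    d: int
    row_labels: tuple[str, str] = ("row1", "row2")
    col_labels: tuple[str, str] = ("col1", "col2")

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise InputError(f"counts must be nonnegative integers, got {v}")
        if not all(self.row_labels) or not all(self.col_labels):
            raise InputError("row/column labels must be non-empty")

    def to_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class TestResult:
    p_value: float
    alternative: str
    method: str
    statistic: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise InputError(f"p-value {self.p_value} outside [0, 1]")


def _credit_correct(credit: float, tie_policy: str) -> Optional[bool]:
    """True/False for correct/incorrect; None when the pair is dropped."""
    if credit == 1.0:
        return True
    if credit == 0.0:
        return False
    if tie_policy == "incorrect":
        return False
    if tie_policy == "exclude":
        return None
    raise InputError(f"unknown tie_policy {tie_policy!r}")


def build_comparison_tables(
    verdicts_a: Sequence[PairVerdict],
    verdicts_b: Sequence[PairVerdict],
    tie_policy: str = "incorrect",
) -> tuple[ContingencyTable2x2, ContingencyTable2x2]:
    """Marginal and paired tables from two verdict lists on the same pairs.

    Verdicts are aligned by (hi, lo); a mismatch in pair coverage raises
    :class:`AlignmentError` listing the symmetric difference.
    """
    map_a = {v.pair.key: v for v in verdicts_a}
    map_b = {v.pair.key: v for v in verdicts_b}
    if set(map_a) != set(map_b):
        diff = sorted(set(map_a) ^ set(map_b))
        raise AlignmentError(
            f"verdict lists cover different pairs; symmetric difference: {diff}"
        )

    a_corr = a_inc = b_corr = b_inc = 0
    both = only_a = only_b = neither = 0
    for key in map_a:
        ca = _credit_correct(map_a[key].credit, tie_policy)
        cb = _credit_correct(map_b[key].credit, tie_policy)
        if ca is not None:
            a_corr += ca
            a_inc += not ca
        if cb is not None:
            b_corr += cb
            b_inc += not cb
        if ca is None or cb is None:
            continue
        both += ca and cb
        only_a += ca and not cb
        only_b += cb and not ca
        neither += not ca and not cb

    marginal = ContingencyTable2x2(
        a=a_corr, b=a_inc, c=b_corr, d=b_inc,
        row_labels=("model A", "model B"),
        col_labels=("correct", "incorrect"),
    )
    paired = ContingencyTable2x2(
        a=both, b=only_a, c=only_b, d=neither,
        row_labels=("A correct", "A incorrect"),
        col_labels=("B correct", "B incorrect"),
    )
    return marginal, paired


def fisher_exact(
    table: ContingencyTable2x2, alternative: str = "two_sided"
) -> TestResult:
    """Fisher's exact test on the table.

    Exact hypergeometric tail probability; the two-sided p sums all tables
    with the given margins whose probability does not exceed the observed
    table's.  ``alternative`` refers to the odds ratio of the (row1, col1)
    cell: 'greater' tests enrichment of that cell.
    """
    alt = {"two_sided": "two-sided", "greater": "greater", "less": "less"}
    if alternative not in alt:
        raise InputError(f"alternative must be one of {sorted(alt)}")
    odds, p = stats.fisher_exact(table.to_array(), alternative=alt[alternative])
    return TestResult(
        p_value=float(p),
        statistic=float(odds) if np.isfinite(odds) else None,
        alternative=alternative,
        method="fisher_exact",
    )


def mcnemar(paired: ContingencyTable2x2) -> TestResult:
    """Exact McNemar test on the paired table's discordant cells.

    Under the null that both models are equally likely to be the sole
    correct one, the smaller discordant count is Binomial(b + c, 1/2);
    the p-value is the exact two-sided binomial tail.  Concordant cells
    are ignored.  b = c = 0 gives p = 1.
    """
    b, c = paired.b, paired.c
    n = b + c
    if n == 0:
        return TestResult(
            p_value=1.0, statistic=0.0, alternative="two_sided",
            method="mcnemar_exact",
        )
    p = stats.binomtest(min(b, c), n, 0.5, alternative="two-sided").pvalue
    return TestResult(
        p_value=float(min(p, 1.0)),
        statistic=float(min(b, c)),
        alternative="two_sided",
        method="mcnemar_exact",
    )


def compare_correctness_tallies(
    correct_a: int,
    incorrect_a: int,
    correct_b: int,
    incorrect_b: int,
    alternative: str = "greater",
) -> TestResult:
    """One-sided Fisher test on two correct/incorrect tallies as columns.

    Columns are the two tallies exactly as given (they may overlap, e.g.
    an all-pairs column versus a matched-subset column); the default
    alternative 'greater' tests whether tally A has a larger fraction of
    correctly ranked pairs than tally B.
    """
    table = ContingencyTable2x2(
        a=correct_a, b=correct_b, c=incorrect_a, d=incorrect_b,
        row_labels=("correct", "incorrect"),
        col_labels=("tally A", "tally B"),
    )
    return fisher_exact(table, alternative=alternative)
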