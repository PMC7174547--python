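"""Classifier-comparison statistics on count tables.

Two classifiers (or a classifier and an expert) are compared through
integer count tables: Pearson's chi-squared on sigh / non-sigh count
tables, and McNemar's test on a 2x2 successes/failures matrix.

Notes on conventions
--------------------
* The Yates continuity correction for chi-squared applies only when
  df = 1, matching standard statistical-package behaviour; each observed
  count is moved up to 0.5 toward its expectation, never past it, so two
  identical rows give a statistic of exactly 0.
* :func:`mcnemar` computes the textbook statistic on whatever 2x2 table it
  is given: (|b - c| - 1)^2 / (b + c) with continuity correction (clamped
  at 0 when |b - c| <= 1), or (b - c)^2 / (b + c) without, where b and c
  are the off-diagonal entries.  Two table builders are provided:
  :func:`successes_failures_table` stacks each classifier's (successes,
  failures) row against a reference — the off-diagonals are then one
  classifier's failures and the other's successes — while
  :func:`discordance_table` builds the orthodox paired-discordance table
  whose off-diagonals count bursts on which exactly one classifier is
  right.  Choose the builder that matches the analysis you want; the two
  are NOT equivalent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2, chi2_contingency


@dataclass(frozen=True)
class ContingencyTable:
    """r x c table of non-negative integer counts."""

    counts: np.ndarray
    row_labels: tuple[str, ...] | None = None
    col_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
            raise ValueError("contingency table must be at least 2x2")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if counts.sum() == 0:
            raise ValueError("contingency table is all zeros")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


@dataclass(frozen=True)
class TestResult:
    """Statistic, degrees of freedom and p-value of a count-table test."""

    statistic: float
    df: int
    p_value: float
    correction: bool

    def as_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "df": self.df,
            "p": self.p_value,
            "correction": self.correction,
        }


def chi_squared(
    table: ContingencyTable, continuity_correction: bool = True
) -> TestResult:
    """Pearson's chi-squared test of homogeneity on a count table.

    The continuity correction takes effect only on 2x2 tables (df = 1).
    Raises on tables with a zero row or column margin.
    """
    counts = table.counts
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: zero row or column margin")
    res = chi2_contingency(counts, correction=continuity_correction)
    df = int(res.dof)
    return TestResult(
        statistic=float(res.statistic),
        df=df,
        p_value=float(res.pvalue),
        correction=bool(continuity_correction and df == 1),
    )


def mcnemar(
    table: ContingencyTable, continuity_correction: bool = True
) -> TestResult:
    """McNemar's chi-squared statistic from the off-diagonals of a 2x2 table.

    With the continuity correction the statistic is
    ``(|b - c| - 1)^2 / (b + c)``; without it, ``(b - c)^2 / (b + c)``.
    df is always 1.  The corrected form follows the convention of R's
    ``mcnemar.test`` and statsmodels: no clamping, so in the degenerate
    case ``|b - c| < 1`` the corrected statistic (1/(b+c)) exceeds the
    uncorrected 0.
    """
    if table.shape != (2, 2):
        raise ValueError("McNemar's test needs a 2x2 table")
    b = int(table.counts[0, 1])
    c = int(table.counts[1, 0])
    if b + c == 0:
        raise ValueError("no discordance: both off-diagonal counts are zero")
    if continuity_correction:
        statistic = (abs(b - c) - 1) ** 2 / (b + c)
    else:
        statistic = (b - c) ** 2 / (b + c)
    return TestResult(
        statistic=float(statistic),
        df=1,
        p_value=float(chi2.sf(statistic, 1)),
        correction=continuity_correction,
    )


def _check_vocabulary(predicted, reference, labels) -> None:
    seen = set(predicted) | set(reference)
    if not seen <= set(labels):
        raise ValueError(
            f"label vocabulary mismatch: found {sorted(seen - set(labels))}, "
            f"expected subset of {list(labels)}"
        )


def confusion_vs_reference(
    predicted,
    reference,
    labels: tuple[str, str] = ("sigh", "non-sigh"),
) -> ContingencyTable:
    """2x2 confusion matrix of predicted (rows) against reference (columns)."""
    predicted = list(predicted)
    reference = list(reference)
    if len(predicted) != len(reference):
        raise ValueError(
            f"length mismatch: {len(predicted)} predicted vs "
            f"{len(reference)} reference labels"
        )
    _check_vocabulary(predicted, reference, labels)
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((2, 2), dtype=int)
    for p, r in zip(predicted, reference):
        counts[index[p], index[r]] += 1
    return ContingencyTable(counts, row_labels=labels, col_labels=labels)


def successes_failures(predicted, reference) -> tuple[int, int]:
    """(n correct, n incorrect) of one classification against a reference."""
    predicted = list(predicted)
    reference = list(reference)
    if len(predicted) != len(reference):
        raise ValueError("length mismatch between predicted and reference")
    n_success = sum(p == r for p, r in zip(predicted, reference))
    return n_success, len(predicted) - n_success


def successes_failures_table(
    predicted_a, predicted_b, reference
) -> ContingencyTable:
    """Stack two classifiers' (successes, failures) rows into a 2x2 table."""
    rows = [
        successes_failures(predicted_a, reference),
        successes_failures(predicted_b, reference),
    ]
    return ContingencyTable(
        np.array(rows, dtype=int),
        row_labels=("classifier_a", "classifier_b"),
        col_labels=("success", "failure"),
    )


def discordance_table(predicted_a, predicted_b, reference) -> ContingencyTable:
    """Paired-discordance 2x2 table: rows = A right/wrong, cols = B right/wrong."""
    predicted_a = list(predicted_a)
    predicted_b = list(predicted_b)
    reference = list(reference)
    if not len(predicted_a) == len(predicted_b) == len(reference):
        raise ValueError("predicted and reference label lists differ in length")
    counts = np.zeros((2, 2), dtype=int)
    for a, b_, r in zip(predicted_a, predicted_b, reference):
        counts[int(a != r), int(b_ != r)] += 1
    return ContingencyTable(
        counts,
        row_labels=("a_correct", "a_wrong"),
        col_labels=("b_correct", "b_wrong"),
    )


def bonferroni(p_value: float, n_comparisons: int) -> float:
    """Bonferroni-adjusted p-value, capped at 1."""
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be positive")
    return min(1.0, p_value * n_comparisons)
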