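"""Agreement and comparison statistics for ordinal score prediction.

Covers Spearman rank correlation between a quantification value and the
visual score, the 6x6 contingency table of true vs predicted score with its
accuracy and quadratic-weighted Cohen's kappa, and the exact (binomial)
McNemar test comparing two classifiers on the same slices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

N_SCORES = 6  # ordinal visual scores 0..5


class DegenerateStatisticError(ValueError):
    """Raised when a statistic is undefined for the given data."""


@dataclass(frozen=True)
class ContingencyTable:
    """6x6 counts, rows = true visual score 0-5, columns = predicted."""

    counts: np.ndarray
    n: int = field(init=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (N_SCORES, N_SCORES):
            raise ValueError(f"expected a {N_SCORES}x{N_SCORES} table")
        if np.any(counts < 0):
            raise ValueError("counts must be nonnegative")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "n", int(counts.sum()))

    @classmethod
    def from_pairs(
        cls, true: Sequence[int], predicted: Sequence[int]
    ) -> "ContingencyTable":
        true = np.asarray(true, dtype=int)
        predicted = np.asarray(predicted, dtype=int)
        if true.shape != predicted.shape:
            raise ValueError("true and predicted lengths differ")
        if np.any((true < 0) | (true >= N_SCORES)):
            raise ValueError("scores must lie in 0..5")
        if np.any((predicted < 0) | (predicted >= N_SCORES)):
            raise ValueError("predictions must lie in 0..5")
        counts = np.zeros((N_SCORES, N_SCORES), dtype=np.int64)
        np.add.at(counts, (true, predicted), 1)
        return cls(counts)


@dataclass(frozen=True)
class PairedOutcomes:
    """Per-slice correctness of two classifiers on identical slices.

    ``b`` counts slices where A is correct and B wrong; ``c`` the reverse.
    """

    a_correct: np.ndarray
    b_correct: np.ndarray

    @property
    def b(self) -> int:
        return int(np.sum(self.a_correct & ~self.b_correct))

    @property
    def c(self) -> int:
        return int(np.sum(~self.a_correct & self.b_correct))


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (Pearson on mid-ranks, ties averaged)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateStatisticError(
            "Spearman undefined: a variable has zero rank variance"
        )
    return float(sps.spearmanr(x, y).statistic)


def accuracy(table: ContingencyTable) -> float:
    """Fraction of exact score agreements: trace over total count."""
    if table.n == 0:
        raise DegenerateStatisticError("empty contingency table")
    return float(np.trace(table.counts) / table.n)


def weighted_kappa(table: ContingencyTable) -> float:
    """Quadratic-weighted Cohen's kappa over the full 0-5 ordinal scale.

    kappa = 1 - sum_ij w_ij O_ij / sum_ij w_ij E_ij with w_ij = (i - j)^2
    and E the outer product of the observed marginals.  Categories absent
    from the sample still shape the weights, since the scale is fixed.
    """
    if table.n == 0:
        raise DegenerateStatisticError("empty contingency table")
    obs = table.counts / table.n
    i = np.arange(N_SCORES)
    w = (i[:, None] - i[None, :]) ** 2
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0))
    denom = float((w * exp).sum())
    if denom == 0.0:
        raise DegenerateStatisticError(
            "kappa undefined: all mass in a single category"
        )
    return float(1.0 - (w * obs).sum() / denom)


def mcnemar_exact(b: int, c: int) -> float:
    """Central two-sided exact McNemar p-value on discordant counts.

    Under the null the b discordances out of b + c follow Binomial(b+c, 1/2);
    the central two-sided p doubles the smaller tail and caps at 1.  With no
    discordant pairs the test carries no evidence and p = 1 by convention.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be nonnegative")
    n = b + c
    if n == 0:
        return 1.0
    p = 2.0 * sps.binom.cdf(min(b, c), n, 0.5)
    return float(min(1.0, p))


def paired_outcomes(result_a, result_b) -> PairedOutcomes:
    """Pair two cross-validation results slice-by-slice for McNemar.

    Both results must cover exactly the same slices; records are matched
    on slice identity, not position.
    """
    a = {r.slice_id: r for r in result_a.records}
    b = {r.slice_id: r for r in result_b.records}
    if set(a) != set(b):
        raise ValueError("results cover different slice sets")
    ids = sorted(a)
    a_ok = np.array([a[s].true_score == a[s].predicted_score for s in ids])
    b_ok = np.array([b[s].true_score == b[s].predicted_score for s in ids])
    return PairedOutcomes(a_correct=a_ok, b_correct=b_ok)
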