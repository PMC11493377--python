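"""ROC AUC discrimination of a PROM for the failure outcome.

AUC is the probability that a randomly chosen failure case carries a more
failure-indicative score than a randomly chosen success case, with
half-credit for ties — the Mann-Whitney statistic divided by the number of
failure x success pairs. Scores are first *risk-oriented*: for a
lower-is-better instrument a high raw score already indicates risk; for a
higher-is-better instrument the score is negated. The point estimate is
graded on the five-level scale in common clinical use
(Hosmer-Lemeshow style): <0.6 low, 0.6-0.69 discrete, 0.70-0.79 moderate,
0.80-0.89 good, >=0.9 excellent.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .cohort_io import Orientation, PROMDefinition
from .threshold_engine import EstimationError

__all__ = [
    "AUCCategory",
    "ROCResult",
    "risk_scores",
    "compute_auc",
    "auc_ci",
    "categorize_auc",
]


class AUCCategory(str, Enum):
    LOW = "low"
    DISCRETE = "discrete"
    MODERATE = "moderate"
    GOOD = "good"
    EXCELLENT = "excellent"


@dataclass
class ROCResult:
    prom: str
    auc: float
    ci_lower: float
    ci_upper: float
    category: AUCCategory
    n_pairs: int

    def format(self) -> str:
        """Tabular rendering, e.g. '0.94 (0.89-0.99)'."""
        return f"{self.auc:.2f} ({self.ci_lower:.2f}-{self.ci_upper:.2f})"


def risk_scores(scores: Sequence[float], prom: PROMDefinition) -> np.ndarray:
    """Orient raw scores so that larger values indicate higher failure risk."""
    x = np.asarray(scores, dtype=float)
    if prom.orientation is Orientation.HIGHER_IS_BETTER:
        return -x
    return x


def _validate(scores, outcomes) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if x.ndim != 1 or len(x) != len(y):
        raise EstimationError("scores and outcomes must be equal-length 1-D sequences")
    if not np.all((y == 0.0) | (y == 1.0)):
        raise EstimationError("outcomes must be binary (1 = failure, 0 = success)")
    if y.min() == y.max():
        raise EstimationError("both outcome classes must be present to compute AUC")
    return x, y


def compute_auc(scores: Sequence[float], outcomes: Sequence[float]) -> float:
    """Tie-aware ROC AUC via the rank-sum identity.

    ``scores`` must already be risk-oriented (larger = more failure-like);
    ``outcomes`` codes failure as 1. Equals
    (concordant pairs + 0.5 * tied pairs) / (n_failure * n_success), i.e. the
    trapezoidal area under the empirical ROC curve.
    """
    x, y = _validate(scores, outcomes)
    n_fail = int(y.sum())
    n_succ = len(y) - n_fail
    ranks = rankdata(x, method="average")
    rank_sum_fail = float(ranks[y == 1.0].sum())
    u = rank_sum_fail - n_fail * (n_fail + 1) / 2.0
    return u / (n_fail * n_succ)


def auc_ci(
    scores: Sequence[float],
    outcomes: Sequence[float],
    B: int = 200,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[float, float]:
    """95% percentile interval of the AUC over B stratified bootstrap resamples.

    Resampling is within each outcome class so every resample retains both
    classes; deterministic under ``seed``.
    """
    if B < 2:
        raise EstimationError("bootstrap needs B >= 2 resamples")
    x, y = _validate(scores, outcomes)
    rng = np.random.default_rng(seed)
    fail = x[y == 1.0]
    succ = x[y == 0.0]
    aucs = np.empty(B)
    y_star = np.concatenate([np.ones(len(fail)), np.zeros(len(succ))])
    for b in range(B):
        f_star = fail[rng.integers(0, len(fail), size=len(fail))]
        s_star = succ[rng.integers(0, len(succ), size=len(succ))]
        aucs[b] = compute_auc(np.concatenate([f_star, s_star]), y_star)
    lo, hi = np.quantile(aucs, [0.025, 0.975])
    return float(lo), float(hi)


def categorize_auc(auc: float) -> AUCCategory:
    """Grade an AUC on the five-level discrimination scale.

    Half-open bins keep the function total on [0, 1]:
    [0, 0.6) low, [0.6, 0.7) discrete, [0.7, 0.8) moderate,
    [0.8, 0.9) good, [0.9, 1] excellent.
    """
    if not (0.0 <= auc <= 1.0):
        raise ValueError(f"AUC {auc} outside [0, 1]")
    if auc < 0.6:
        return AUCCategory.LOW
    if auc < 0.7:
        return AUCCategory.DISCRETE
    if auc < 0.8:
        return AUCCategory.MODERATE
    if auc < 0.9:
        return AUCCategory.GOOD
    return AUCCategory.EXCELLENT
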