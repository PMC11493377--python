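"""Cohort data model, anchor dichotomization, CSV I/O and descriptives.

A cohort is one row per knee-arthroplasty procedure: an opaque id, the
patient's answer to the quality-of-life anchor question ("How much did your
knee surgery improve your quality of life?", a 1-6 Likert item), and integer
scores for up to five patient-reported outcome measures (PROMs).

The anchor is dichotomized into the modeled binary outcome: responses 1-4
("worse" through "moderate improvement") are *failure* ("same or worse"),
responses 5-6 ("great improvement", "more than I ever dreamed") are
*success* ("much better"). Failure is the positive/modeled class throughout
the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from fractions import Fraction
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ID_COLUMN = "id"
ANCHOR_COLUMN = "anchor"


class CohortValidationError(ValueError):
    """A cohort table or record violates the data contract."""


class Orientation(str, Enum):
    """Whether a lower or a higher score denotes a better clinical state."""

    LOWER_IS_BETTER = "lower_is_better"
    HIGHER_IS_BETTER = "higher_is_better"


class Outcome(str, Enum):
    """Dichotomized anchor outcome; FAILURE ('same or worse') is modeled."""

    FAILURE = "failure"
    SUCCESS = "success"


@dataclass(frozen=True)
class PROMDefinition:
    """A scored instrument: name, closed integer score range, orientation."""

    name: str
    min_score: int
    max_score: int
    orientation: Orientation

    def __post_init__(self) -> None:
        if not (int(self.min_score) == self.min_score and int(self.max_score) == self.max_score):
            raise CohortValidationError(f"{self.name}: score bounds must be integers")
        if self.min_score >= self.max_score:
            raise CohortValidationError(
                f"{self.name}: min_score {self.min_score} must be < max_score {self.max_score}"
            )

    @property
    def grid(self) -> np.ndarray:
        """Every integer score in the instrument's range, ascending."""
        return np.arange(self.min_score, self.max_score + 1)

    def validate_score(self, value: float, where: str = "") -> int:
        loc = f" ({where})" if where else ""
        if not np.isfinite(value) or round(float(value)) != float(value):
            raise CohortValidationError(
                f"{self.name}: score {value!r} is not an integer{loc}"
            )
        v = int(value)
        if not (self.min_score <= v <= self.max_score):
            raise CohortValidationError(
                f"{self.name}: score {v} outside range [{self.min_score}, {self.max_score}]{loc}"
            )
        return v


#: The five instruments analyzed: the three WOMAC dimensions (lower = better),
#: the Kujala anterior-knee-pain score and the KOOS quality-of-life subscale
#: (higher = better).
BUILTIN_PROMS: dict[str, PROMDefinition] = {
    d.name: d
    for d in (
        PROMDefinition("womac_pain", 0, 20, Orientation.LOWER_IS_BETTER),
        PROMDefinition("womac_stiffness", 0, 8, Orientation.LOWER_IS_BETTER),
        PROMDefinition("womac_function", 0, 68, Orientation.LOWER_IS_BETTER),
        PROMDefinition("kujala", 0, 100, Orientation.HIGHER_IS_BETTER),
        PROMDefinition("koos_ql", 0, 100, Orientation.HIGHER_IS_BETTER),
    )
}

ANCHOR_LEVELS = frozenset(range(1, 7))
_FAILURE_LEVELS = frozenset({1, 2, 3, 4})


def dichotomize_anchor(value: int, record_id: str | None = None) -> Outcome:
    """Map a 1-6 anchor response to the binary outcome.

    1-4 -> FAILURE ("same or worse"); 5-6 -> SUCCESS ("much better").
    """
    where = f" in record {record_id!r}" if record_id is not None else ""
    try:
        v = int(value)
    except (TypeError, ValueError):
        raise CohortValidationError(f"anchor response {value!r}{where} is not an integer")
    if float(v) != float(value) or v not in ANCHOR_LEVELS:
        raise CohortValidationError(
            f"anchor response {value!r}{where} outside the 1..6 Likert scale"
        )
    return Outcome.FAILURE if v in _FAILURE_LEVELS else Outcome.SUCCESS


@dataclass(frozen=True)
class PatientRecord:
    """One procedure: id, raw anchor level, derived outcome, PROM scores."""

    id: str
    anchor: int
    outcome: Outcome
    scores: Mapping[str, int] = field(default_factory=dict)


@dataclass
class Cohort:
    """Patient records plus derived baseline quantities."""

    records: list[PatientRecord]
    prom_defs: dict[str, PROMDefinition] = field(
        default_factory=lambda: dict(BUILTIN_PROMS)
    )
    n_dropped_missing_anchor: int = 0

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def n_failure(self) -> int:
        return sum(r.outcome is Outcome.FAILURE for r in self.records)

    @property
    def p0(self) -> float:
        """Baseline failure proportion n_failure / n."""
        if self.n == 0:
            raise CohortValidationError("empty cohort has no baseline probability")
        return self.n_failure / self.n

    def subset_complete(self, prom: PROMDefinition) -> tuple[np.ndarray, np.ndarray]:
        """Complete-case data for one PROM.

        Returns (scores, outcomes) where outcomes is 1 for failure, 0 for
        success, over the records that have a score for `prom`.
        """
        pairs = [
            (r.scores[prom.name], 1.0 if r.outcome is Outcome.FAILURE else 0.0)
            for r in self.records
            if prom.name in r.scores
        ]
        if not pairs:
            raise CohortValidationError(f"no records carry a {prom.name} score")
        arr = np.array(pairs, dtype=float)
        return arr[:, 0], arr[:, 1]

    def to_frame(self) -> pd.DataFrame:
        """Tidy one-row-per-procedure table in the interchange CSV layout."""
        names = list(self.prom_defs)
        rows = []
        for r in self.records:
            row: dict[str, object] = {ID_COLUMN: r.id, ANCHOR_COLUMN: r.anchor}
            for name in names:
                row[name] = r.scores.get(name, pd.NA)
            rows.append(row)
        return pd.DataFrame(rows, columns=[ID_COLUMN, ANCHOR_COLUMN, *names])


@dataclass(frozen=True)
class BaselineProbability:
    """Exact baseline failure fraction with its rendered percentage."""

    n: int
    n_failure: int
    fraction: Fraction
    value: float
    percent: str


def proportion(numerator: int, denominator: int) -> Fraction:
    """Exact proportion as a Fraction; denominator must be positive."""
    if denominator <= 0:
        raise CohortValidationError("proportion denominator must be positive")
    if not (0 <= numerator <= denominator):
        raise CohortValidationError(
            f"numerator {numerator} outside [0, {denominator}]"
        )
    return Fraction(numerator, denominator)


def format_percent(frac: Fraction | float, decimals: int = 2) -> str:
    """Render a proportion as a percentage string, e.g. 21/161 -> '13.04%'."""
    return f"{float(frac) * 100:.{decimals}f}%"


def baseline_probability(cohort: Cohort) -> BaselineProbability:
    """Cohort-wide failure proportion p0 = n_failure / n, exact and rendered."""
    if cohort.n == 0:
        raise CohortValidationError("empty cohort has no baseline probability")
    frac = proportion(cohort.n_failure, cohort.n)
    return BaselineProbability(
        n=cohort.n,
        n_failure=cohort.n_failure,
        fraction=frac,
        value=float(frac),
        percent=format_percent(frac, 2),
    )


@dataclass
class GroupedECDF:
    """Cumulative frequency of a PROM score split by outcome group.

    For each observed score value (ascending), the number of failures and
    successes scoring at or below that value, and the cumulative proportion
    of all records analyzed for this PROM.
    """

    prom: str
    values: np.ndarray
    cum_failure: np.ndarray
    cum_success: np.ndarray
    cum_proportion: np.ndarray
    n_analyzed: int

    def to_frame(self) -> pd.DataFrame:
        """Tidy (score, group, cumulative_count, cumulative_proportion) table."""
        total = self.cum_failure + self.cum_success
        rows = []
        for grp, cum in (("failure", self.cum_failure), ("success", self.cum_success)):
            for v, c, t in zip(self.values, cum, total):
                rows.append(
                    {
                        "score": int(v),
                        "group": grp,
                        "cumulative_count": int(c),
                        "cumulative_proportion": t / self.n_analyzed,
                    }
                )
        return pd.DataFrame(rows)


def grouped_ecdf(cohort: Cohort, prom: PROMDefinition) -> GroupedECDF:
    """Group-wise cumulative frequencies over observed score values."""
    scores, outcomes = cohort.subset_complete(prom)
    values = np.unique(scores)
    fail_scores = scores[outcomes == 1.0]
    succ_scores = scores[outcomes == 0.0]
    cum_fail = np.array([(fail_scores <= v).sum() for v in values])
    cum_succ = np.array([(succ_scores <= v).sum() for v in values])
    n = len(scores)
    return GroupedECDF(
        prom=prom.name,
        values=values.astype(int),
        cum_failure=cum_fail,
        cum_success=cum_succ,
        cum_proportion=(cum_fail + cum_succ) / n,
        n_analyzed=n,
    )


def _coerce_anchor(raw: object, line_no: int) -> int | None:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)) or raw is pd.NA:
        return None
    if isinstance(raw, str) and raw.strip() == "":
        return None
    try:
        v = float(raw)
    except (TypeError, ValueError):
        raise CohortValidationError(f"line {line_no}: anchor {raw!r} is not numeric")
    if not np.isfinite(v):
        return None
    if v != int(v):
        raise CohortValidationError(f"line {line_no}: anchor {raw!r} is not an integer")
    return int(v)


def load_cohort(
    path: str,
    defs: Mapping[str, PROMDefinition] | Iterable[PROMDefinition] | None = None,
) -> Cohort:
    """Read and validate a patient cohort CSV.

    The header must name an ``id`` column, an ``anchor`` column (integer 1-6)
    and any subset of the known PROM columns. Records with a missing anchor
    are dropped and counted (logged); a record missing an individual PROM
    score is retained and simply excluded from that PROM's analyses.
    Out-of-range or non-integer scores raise with the offending line number.
    """
    if defs is None:
        defs = BUILTIN_PROMS
    elif not isinstance(defs, Mapping):
        defs = {d.name: d for d in defs}
    else:
        defs = dict(defs)

    try:
        df = pd.read_csv(path, dtype=object)
    except Exception as exc:  # pragma: no cover - message passthrough
        raise CohortValidationError(f"cannot parse cohort file {path!r}: {exc}") from exc

    for required in (ID_COLUMN, ANCHOR_COLUMN):
        if required not in df.columns:
            raise CohortValidationError(f"{path}: missing required column {required!r}")
    unknown = [c for c in df.columns if c not in (ID_COLUMN, ANCHOR_COLUMN) and c not in defs]
    if unknown:
        raise CohortValidationError(
            f"{path}: unknown PROM column(s) {unknown}; known: {sorted(defs)}"
        )
    prom_cols = [c for c in df.columns if c in defs]

    records: list[PatientRecord] = []
    n_dropped = 0
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2  # header is line 1
        rowd = dict(zip(df.columns, row))
        rid = str(rowd[ID_COLUMN])
        anchor = _coerce_anchor(rowd[ANCHOR_COLUMN], line_no)
        if anchor is None:
            n_dropped += 1
            continue
        outcome = dichotomize_anchor(anchor, record_id=rid)
        scores: dict[str, int] = {}
        for col in prom_cols:
            raw = rowd[col]
            if raw is None or raw is pd.NA or (isinstance(raw, float) and np.isnan(raw)):
                continue
            if isinstance(raw, str):
                if raw.strip() == "":
                    continue
                try:
                    raw = float(raw)
                except ValueError:
                    raise CohortValidationError(
                        f"line {line_no}: {col} value {raw!r} is not numeric"
                    )
            scores[col] = defs[col].validate_score(float(raw), where=f"line {line_no}")
        records.append(PatientRecord(id=rid, anchor=anchor, outcome=outcome, scores=scores))

    if n_dropped:
        logger.warning("%s: dropped %d record(s) with missing anchor", path, n_dropped)
    return Cohort(records=records, prom_defs=dict(defs), n_dropped_missing_anchor=n_dropped)


def write_cohort(cohort: Cohort, path: str) -> None:
    """Write a cohort in the exact CSV dialect :func:`load_cohort` reads."""
    df = cohort.to_frame()
    df.to_csv(path, index=False)
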