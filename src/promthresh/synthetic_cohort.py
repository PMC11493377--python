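"""Seeded synthetic cohorts with the statistical structure the pipeline assumes.

Scores are bounded integers drawn from a discretized, range-truncated normal
(location/spread per instrument); the binary failure outcome is drawn through
a known logistic link, so every downstream estimate has a ground truth to be
checked against. Two layouts are provided:

* a single-PROM layout (``simulate_prom``) where the outcome is Bernoulli in
  that PROM's score with user-specified true coefficients — the workhorse of
  the estimator-validation suites; and
* a multi-PROM cohort (``generate_cohort`` / ``make_paper_like_cohort``)
  where one *outcome PROM* drives the logistic link and the remaining
  instruments load on a shared latent severity factor, so each correlates
  with the outcome the way concurrently administered questionnaires do.

``make_paper_like_cohort`` emulates the study conditions: n = 161 knees,
all five instruments, and an intercept calibrated by root-finding so the
expected number of failures over the realized scores is exactly 21 (13.04%).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import truncnorm

from .cohort_io import (
    BUILTIN_PROMS,
    Cohort,
    CohortValidationError,
    Orientation,
    PatientRecord,
    PROMDefinition,
    dichotomize_anchor,
)

__all__ = [
    "PROMSim",
    "GeneratorConfig",
    "generate_scores",
    "generate_outcomes",
    "generate_cohort",
    "simulate_prom",
    "make_paper_like_cohort",
    "PAPER_N",
    "PAPER_N_FAILURE",
]

PAPER_N = 161
PAPER_N_FAILURE = 21

# Anchor levels drawn within each outcome class (levels 1-4 are failure,
# 5-6 success); weights are arbitrary but fixed so cohorts are reproducible.
_FAILURE_ANCHOR_LEVELS = np.array([1, 2, 3, 4])
_FAILURE_ANCHOR_WEIGHTS = np.array([0.10, 0.30, 0.35, 0.25])
_SUCCESS_ANCHOR_LEVELS = np.array([5, 6])
_SUCCESS_ANCHOR_WEIGHTS = np.array([0.60, 0.40])


@dataclass(frozen=True)
class PROMSim:
    """Score-marginal and (optional) true-link parameters for one instrument."""

    location: float
    spread: float
    beta0: float | None = None
    beta1: float = 0.0


@dataclass
class GeneratorConfig:
    """Full recipe for a synthetic cohort; the seed is mandatory."""

    n: int
    sims: Mapping[str, PROMSim]
    seed: int
    prom_defs: Mapping[str, PROMDefinition] = field(
        default_factory=lambda: dict(BUILTIN_PROMS)
    )
    outcome_prom: str | None = None  # defaults to the first PROM in `sims`
    latent_weight: float = 0.0  # shared severity loading in [0, 1)
    target_failure_rate: float | None = None  # calibrates the intercept if set

    def __post_init__(self) -> None:
        if self.n < 1:
            raise CohortValidationError("cohort size n must be >= 1")
        if not self.sims:
            raise CohortValidationError("at least one PROM must be simulated")
        unknown = set(self.sims) - set(self.prom_defs)
        if unknown:
            raise CohortValidationError(f"unknown PROM(s) in generator config: {unknown}")
        if not 0.0 <= self.latent_weight < 1.0:
            raise CohortValidationError("latent_weight must lie in [0, 1)")
        if self.outcome_prom is None:
            self.outcome_prom = next(iter(self.sims))
        if self.outcome_prom not in self.sims:
            raise CohortValidationError(f"outcome PROM {self.outcome_prom!r} not simulated")


def generate_scores(
    prom: PROMDefinition,
    n: int,
    location: float,
    spread: float,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Draw n integer scores from a rounded, range-truncated normal.

    spread = 0 degenerates to a point mass at the rounded location (clipped
    into range). Deterministic under a seed or seeded Generator.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    lo, hi = prom.min_score, prom.max_score
    if spread < 0:
        raise CohortValidationError("score spread must be non-negative")
    if spread == 0:
        return np.full(n, int(np.clip(round(location), lo, hi)))
    # truncate on [lo-0.5, hi+0.5] so rounding yields the exact integer support
    a = (lo - 0.5 - location) / spread
    b = (hi + 0.5 - location) / spread
    cont = truncnorm.rvs(a, b, loc=location, scale=spread, size=n, random_state=rng)
    return np.clip(np.rint(cont), lo, hi).astype(int)


def generate_outcomes(
    scores: Sequence[float],
    beta0: float,
    beta1: float,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Bernoulli failure outcomes through the logistic link in the score.

    Returns a float array with 1 = failure, independent across patients,
    deterministic under the seed.
    """
    if not (np.isfinite(beta0) and np.isfinite(beta1)):
        raise CohortValidationError("true coefficients must be finite")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    x = np.asarray(scores, dtype=float)
    p = expit(beta0 + beta1 * x)
    return (rng.random(len(x)) < p).astype(float)


def calibrate_intercept(scores: Sequence[float], beta1: float, target_rate: float) -> float:
    """Intercept making the mean failure probability over `scores` equal target_rate."""
    x = np.asarray(scores, dtype=float)
    if not 0.0 < target_rate < 1.0:
        raise CohortValidationError("target failure rate must be in (0, 1)")

    def gap(b0: float) -> float:
        return float(np.mean(expit(b0 + beta1 * x))) - target_rate

    return brentq(gap, -60.0, 60.0, xtol=1e-12)


def simulate_prom(
    prom: PROMDefinition,
    n: int,
    location: float,
    spread: float,
    beta0: float,
    beta1: float,
    seed: int | np.random.SeedSequence,
) -> tuple[np.ndarray, np.ndarray]:
    """Single-PROM layout: scores plus outcomes with known coefficients."""
    rng = np.random.default_rng(seed)
    x = generate_scores(prom, n, location, spread, rng)
    y = generate_outcomes(x, beta0, beta1, rng)
    return x, y


def _anchor_levels(failure: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    anchors = np.empty(len(failure), dtype=int)
    n_fail = int(failure.sum())
    anchors[failure == 1.0] = rng.choice(
        _FAILURE_ANCHOR_LEVELS, size=n_fail, p=_FAILURE_ANCHOR_WEIGHTS
    )
    anchors[failure == 0.0] = rng.choice(
        _SUCCESS_ANCHOR_LEVELS, size=len(failure) - n_fail, p=_SUCCESS_ANCHOR_WEIGHTS
    )
    return anchors


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Draw a full multi-PROM cohort from a generator config.

    With ``latent_weight`` w > 0, each patient carries a latent severity
    z ~ N(0,1) and each instrument's continuous score is
    location + spread * (w * s * z + sqrt(1-w^2) * eps), where s is +1 for
    lower-is-better instruments and -1 otherwise, then rounded and clipped —
    so worse severity raises WOMAC-style scores and lowers Kujala-style ones.
    Outcomes follow the logistic link in the outcome PROM's realized score.
    """
    rng = np.random.default_rng(config.seed)
    n, w = config.n, config.latent_weight
    z = rng.standard_normal(n) if w > 0 else np.zeros(n)

    scores: dict[str, np.ndarray] = {}
    for name, sim in config.sims.items():
        prom = config.prom_defs[name]
        if w == 0:
            scores[name] = generate_scores(prom, n, sim.location, sim.spread, rng)
        else:
            sgn = 1.0 if prom.orientation is Orientation.LOWER_IS_BETTER else -1.0
            eps = rng.standard_normal(n)
            cont = sim.location + sim.spread * (w * sgn * z + np.sqrt(1 - w**2) * eps)
            scores[name] = np.clip(np.rint(cont), prom.min_score, prom.max_score).astype(int)

    sim_out = config.sims[config.outcome_prom]
    x_out = scores[config.outcome_prom]
    beta1 = sim_out.beta1
    if sim_out.beta0 is not None:
        beta0 = sim_out.beta0
    elif config.target_failure_rate is not None:
        beta0 = calibrate_intercept(x_out, beta1, config.target_failure_rate)
    else:
        raise CohortValidationError(
            "outcome PROM needs beta0 or a target failure rate to calibrate it"
        )
    failure = generate_outcomes(x_out, beta0, beta1, rng)
    anchors = _anchor_levels(failure, rng)

    width = len(str(n))
    records = [
        PatientRecord(
            id=f"S{i + 1:0{width}d}",
            anchor=int(anchors[i]),
            outcome=dichotomize_anchor(int(anchors[i])),
            scores={name: int(scores[name][i]) for name in config.sims},
        )
        for i in range(n)
    ]
    defs = {name: config.prom_defs[name] for name in config.sims}
    return Cohort(records=records, prom_defs=defs)


#: Score marginals emulating the study cohort's cumulative-frequency figures
#: (most knees do well: low WOMAC scores, high Kujala/KOOS-QL).
PAPER_LIKE_SIMS: dict[str, PROMSim] = {
    "womac_pain": PROMSim(location=3.0, spread=3.5, beta1=0.5),
    "womac_stiffness": PROMSim(location=1.0, spread=1.6),
    "womac_function": PROMSim(location=9.0, spread=9.0),
    "kujala": PROMSim(location=73.0, spread=15.0),
    "koos_ql": PROMSim(location=62.0, spread=20.0),
}


def make_paper_like_cohort(seed: int) -> Cohort:
    """A 161-knee cohort with all five instruments and ~13% expected failures.

    The intercept of the outcome link (through WOMAC-Pain) is calibrated so
    the expected failure count over the realized scores is exactly 21/161;
    the observed count then varies binomially around it across seeds.
    """
    config = GeneratorConfig(
        n=PAPER_N,
        sims=dict(PAPER_LIKE_SIMS),
        seed=seed,
        outcome_prom="womac_pain",
        latent_weight=0.75,
        target_failure_rate=PAPER_N_FAILURE / PAPER_N,
    )
    return generate_cohort(config)
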