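"""Logistic threshold engine: fit, bootstrap covariance, delta-method band,
and the TIS/TIF rule.

The model is a univariable logistic regression of the binary failure outcome
("same or worse" quality of life) on one PROM score x:

    logit P(failure | x) = beta0 + beta1 * x

The coefficient covariance is estimated either from the observed information
at the MLE or by case-resampling bootstrap (default B = 200 resamples). The
failure probability p(x) = expit(beta0 + beta1*x) gets a pointwise 95%
confidence band over every integer score in the instrument's range via the
delta method on the probability scale:

    Var p(x) ~= g' Sigma g,   g = p(1-p) * (1, x)

The threshold for increased success (TIS) is the first score — scanning from
the instrument's good extreme — at which the band stops lying entirely below
the cohort baseline failure probability p0; the threshold for increased
failure (TIF) mirrors it from the bad extreme with the band entirely above
p0. Bounds are reported with a strict relation ("<4" means scores 0-3
qualify), matching how such cutoffs are tabulated clinically.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Sequence

import numpy as np
from scipy.special import expit, logit
from scipy.stats import norm

from .cohort_io import Cohort, Orientation, PROMDefinition

__all__ = [
    "AnalysisSettings",
    "CovSource",
    "EstimationError",
    "SeparationError",
    "LogisticFit",
    "ProbabilityCurve",
    "ThresholdResult",
    "inv_logit",
    "fit_logistic_mle",
    "bootstrap_covariance",
    "probability_curve",
    "find_thresholds",
    "run_prom_analysis",
]

# IRLS convergence/divergence control
MAX_IRLS_ITER = 100
LL_TOL = 1e-10
GRAD_TOL = 1e-8
SEPARATION_BETA_BOUND = 30.0


class EstimationError(RuntimeError):
    """The logistic fit or a downstream stage cannot be computed."""


class SeparationError(EstimationError):
    """Complete or quasi-complete separation: the MLE does not exist."""


class CovSource(str, Enum):
    BOOTSTRAP = "bootstrap"
    MODEL_INFORMATION = "model_information"


def inv_logit(eta):
    """Logistic link inverse: 1 / (1 + exp(-eta)), elementwise."""
    arr = np.asarray(eta, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("inv_logit requires finite input")
    out = expit(arr)
    return float(out) if np.isscalar(eta) or arr.ndim == 0 else out


@dataclass
class LogisticFit:
    """MLE of the univariable logistic model with a coefficient covariance."""

    beta0: float
    beta1: float
    cov: np.ndarray
    cov_source: CovSource
    n_used: int
    converged: bool
    n_iter: int
    loglik: float
    n_boot_requested: int = 0
    n_boot_converged: int = 0

    @property
    def beta(self) -> np.ndarray:
        return np.array([self.beta0, self.beta1])

    def predict(self, x) -> np.ndarray:
        return inv_logit(self.beta0 + self.beta1 * np.asarray(x, dtype=float))


def _validate_xy(scores, outcomes) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or len(x) != len(y):
        raise EstimationError("scores and outcomes must be equal-length 1-D sequences")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise EstimationError("scores and outcomes must be finite")
    if not np.all((y == 0.0) | (y == 1.0)):
        raise EstimationError("outcomes must be binary (1 = failure, 0 = success)")
    if y.min() == y.max():
        raise EstimationError("both outcome classes must be present")
    if x.min() == x.max():
        raise EstimationError("scores are all identical; slope is unidentifiable")
    return x, y


def _loglik(eta: np.ndarray, y: np.ndarray) -> float:
    # y*eta - log(1 + exp(eta)), numerically stable
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic_mle(scores: Sequence[float], outcomes: Sequence[float]) -> LogisticFit:
    """Maximum-likelihood logistic fit by iteratively reweighted least squares.

    ``outcomes`` codes failure as 1 and success as 0. Convergence requires the
    log-likelihood change below 1e-10 and gradient norm below 1e-8. Separation
    is declared when |beta| exceeds 30 on the logit scale or IRLS fails to
    converge within 100 iterations. The returned covariance is the inverse
    observed information at the MLE (``cov_source=model_information``).
    """
    x, y = _validate_xy(scores, outcomes)
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    ll = _loglik(X @ beta, y)
    converged = False
    n_iter = 0

    for n_iter in range(1, MAX_IRLS_ITER + 1):
        eta = X @ beta
        p = expit(eta)
        grad = X.T @ (y - p)
        w = p * (1.0 - p)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(
                "singular information matrix; data are separated or degenerate"
            ) from exc
        # step-halving keeps the likelihood non-decreasing; decreases within
        # float round-off of ll are accepted so Newton can finish quadratically
        new_beta = beta + step
        new_ll = _loglik(X @ new_beta, y)
        noise = 1e-10 * (1.0 + abs(ll))
        halvings = 0
        while new_ll < ll - noise and halvings < 30:
            step *= 0.5
            new_beta = beta + step
            new_ll = _loglik(X @ new_beta, y)
            halvings += 1
        beta = new_beta
        if np.max(np.abs(beta)) > SEPARATION_BETA_BOUND:
            raise SeparationError(
                f"|beta| exceeded {SEPARATION_BETA_BOUND} on the logit scale; "
                "complete or quasi-complete separation"
            )
        d_ll, ll = new_ll - ll, new_ll
        grad_new = X.T @ (y - expit(X @ beta))
        if abs(d_ll) < LL_TOL and np.linalg.norm(grad_new) < GRAD_TOL:
            converged = True
            break

    if not converged:
        raise SeparationError(
            f"IRLS did not converge in {MAX_IRLS_ITER} iterations"
        )

    p = expit(X @ beta)
    w = p * (1.0 - p)
    H = (X * w[:, None]).T @ X
    cov = np.linalg.inv(H)
    return LogisticFit(
        beta0=float(beta[0]),
        beta1=float(beta[1]),
        cov=cov,
        cov_source=CovSource.MODEL_INFORMATION,
        n_used=len(x),
        converged=converged,
        n_iter=n_iter,
        loglik=ll,
    )


@dataclass
class BootstrapCovariance:
    cov: np.ndarray
    coefficients: np.ndarray  # (n_converged, 2)
    n_requested: int
    n_converged: int


def bootstrap_covariance(
    scores: Sequence[float],
    outcomes: Sequence[float],
    B: int = 200,
    seed: int | np.random.SeedSequence = 0,
) -> BootstrapCovariance:
    """Case-resampling bootstrap covariance of (beta0, beta1).

    Draws B unstratified resamples of (score, outcome) pairs with
    replacement, refits each, skips resamples where the fit fails
    (separation, a single outcome class), and returns the empirical
    covariance of the converged coefficient pairs. Errors out if fewer than
    B/2 resamples converge. Deterministic under ``seed``.
    """
    if B < 2:
        raise EstimationError("bootstrap needs B >= 2 resamples")
    x, y = _validate_xy(scores, outcomes)
    fit_logistic_mle(x, y)  # the full-data fit must succeed first
    rng = np.random.default_rng(seed)
    n = len(x)
    coefs = []
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        try:
            fit = fit_logistic_mle(x[idx], y[idx])
        except EstimationError:
            continue
        coefs.append([fit.beta0, fit.beta1])
    n_conv = len(coefs)
    if n_conv < B / 2:
        raise EstimationError(
            f"only {n_conv}/{B} bootstrap resamples converged; "
            "covariance would be unreliable"
        )
    arr = np.asarray(coefs)
    cov = np.cov(arr, rowvar=False, ddof=1)
    return BootstrapCovariance(cov=cov, coefficients=arr, n_requested=B, n_converged=n_conv)


@dataclass
class ProbabilityCurve:
    """Failure probability with pointwise delta-method band over a score grid."""

    prom: str
    grid: np.ndarray
    p: np.ndarray
    lower95: np.ndarray
    upper95: np.ndarray
    z: float
    level: float = 0.95
    scale: str = "probability"


def probability_curve(
    fit: LogisticFit,
    prom: PROMDefinition,
    level: float = 0.95,
    scale: str = "probability",
) -> ProbabilityCurve:
    """Delta-method confidence band for p(x) over the full integer score grid.

    On the default probability scale the band is p +/- z*sqrt(g' Sigma g)
    with gradient g = p(1-p)*(1, x), truncated to [0, 1]. ``scale="logit"``
    instead builds a normal band for eta = beta0 + beta1*x and maps it
    through the inverse logit (a sensitivity variant; bounds never need
    truncation there).
    """
    if not 0.0 < level < 1.0:
        raise ValueError("confidence level must be in (0, 1)")
    if scale not in ("probability", "logit"):
        raise ValueError(f"unknown band scale {scale!r}")
    cov = np.asarray(fit.cov, dtype=float)
    if cov.shape != (2, 2):
        raise ValueError("coefficient covariance must be 2x2")
    sym_gap = abs(cov[0, 1] - cov[1, 0])
    if sym_gap > 1e-8 * max(1.0, abs(cov).max()):
        raise ValueError("coefficient covariance must be symmetric")
    eigs = np.linalg.eigvalsh((cov + cov.T) / 2.0)
    if eigs.min() < -1e-8 * max(1.0, eigs.max()):
        raise ValueError("coefficient covariance must be positive semi-definite")

    grid = prom.grid.astype(float)
    z = float(norm.ppf(0.5 + level / 2.0))
    eta = fit.beta0 + fit.beta1 * grid
    p = expit(eta)
    G_eta = np.column_stack([np.ones_like(grid), grid])
    var_eta = np.einsum("ij,jk,ik->i", G_eta, cov, G_eta)
    if var_eta.min() < -1e-12:
        raise EstimationError("negative variance from the covariance quadratic form")
    var_eta = np.clip(var_eta, 0.0, None)

    if scale == "probability":
        se_p = p * (1.0 - p) * np.sqrt(var_eta)
        lower = np.clip(p - z * se_p, 0.0, 1.0)
        upper = np.clip(p + z * se_p, 0.0, 1.0)
    else:
        se_eta = np.sqrt(var_eta)
        lower = expit(eta - z * se_eta)
        upper = expit(eta + z * se_eta)

    return ProbabilityCurve(
        prom=prom.name,
        grid=prom.grid.copy(),
        p=p,
        lower95=lower,
        upper95=upper,
        z=z,
        level=level,
        scale=scale,
    )


@dataclass
class ThresholdResult:
    """TIS/TIF bounds for one PROM against the cohort baseline probability.

    Bounds are the first score NOT in the qualifying run, reported with a
    strict relation: for a lower-is-better instrument TIS "<4" means the
    delta-method band lies entirely below p0 at scores up to 3. The
    probabilities ``p_tis`` / ``p_tif`` (with their CIs) are evaluated at the
    qualifying score adjacent to the bound. A bound is None when no score at
    the relevant extreme qualifies (a valid, inconclusive result).
    """

    prom: str
    p0: float
    tis: int | None
    tis_relation: str
    tif: int | None
    tif_relation: str
    p_tis: float | None = None
    p_tis_ci: tuple[float, float] | None = None
    p_tif: float | None = None
    p_tif_ci: tuple[float, float] | None = None

    def format_bound(self, which: str) -> str:
        bound = self.tis if which == "tis" else self.tif
        rel = self.tis_relation if which == "tis" else self.tif_relation
        return "-" if bound is None else f"{rel}{bound}"


def _leading_run(mask: np.ndarray) -> int:
    """Length of the True-run at the start of a boolean vector."""
    n = 0
    for m in mask:
        if not m:
            break
        n += 1
    return n


def find_thresholds(
    curve: ProbabilityCurve, p0: float, prom: PROMDefinition
) -> ThresholdResult:
    """Apply the TIS/TIF rule to a probability band.

    Scanning from the instrument's *good* extreme, scores qualify for TIS
    while upper95 < p0; scanning from the *bad* extreme, scores qualify for
    TIF while lower95 > p0. Each bound is the first score where the run
    breaks; qualifying runs must be contiguous from the extreme, so isolated
    interior excursions of the band do not create thresholds.
    """
    if not 0.0 < p0 < 1.0:
        raise ValueError("baseline probability must lie strictly inside (0, 1)")
    grid = curve.grid
    if grid[0] != prom.min_score or grid[-1] != prom.max_score:
        raise ValueError("curve grid must span the instrument's full range")

    lower_better = prom.orientation is Orientation.LOWER_IS_BETTER
    # orient so index 0 is the good extreme
    order = slice(None) if lower_better else slice(None, None, -1)
    g = grid[order]
    up = curve.upper95[order]
    lo = curve.lower95[order]
    p = curve.p[order]

    tis_rel, tif_rel = ("<", ">") if lower_better else (">", "<")

    k_tis = _leading_run(up < p0)  # from the good extreme
    k_tif = _leading_run(lo[::-1] > p0)  # from the bad extreme

    tis = tif = None
    p_tis = p_tis_ci = p_tif = p_tif_ci = None
    if k_tis > 0:
        tis = int(g[k_tis]) if k_tis < len(g) else None  # None: whole range qualifies
        j = k_tis - 1
        p_tis, p_tis_ci = float(p[j]), (float(lo[j]), float(up[j]))
    if k_tif > 0:
        tif = int(g[::-1][k_tif]) if k_tif < len(g) else None
        j = len(g) - k_tif
        p_tif, p_tif_ci = float(p[j]), (float(lo[j]), float(up[j]))

    return ThresholdResult(
        prom=prom.name,
        p0=p0,
        tis=tis,
        tis_relation=tis_rel,
        tif=tif,
        tif_relation=tif_rel,
        p_tis=p_tis,
        p_tis_ci=p_tis_ci,
        p_tif=p_tif,
        p_tif_ci=p_tif_ci,
    )


@dataclass
class AnalysisSettings:
    """Tunable knobs of the per-PROM pipeline."""

    n_boot: int = 200
    level: float = 0.95
    cov_source: CovSource = CovSource.BOOTSTRAP
    band_scale: str = "probability"
    seed: int = 0


@dataclass
class PROMAnalysis:
    """Joined per-PROM result: fit, band, thresholds and discrimination."""

    prom: str
    fit: LogisticFit
    curve: ProbabilityCurve
    thresholds: ThresholdResult
    roc: "object" = None  # discrimination.ROCResult; typed loosely to avoid a cycle


def run_prom_analysis(
    cohort: Cohort,
    prom: PROMDefinition,
    settings: AnalysisSettings | None = None,
) -> PROMAnalysis:
    """Complete-case pipeline for one PROM: fit -> covariance -> band -> TIS/TIF -> AUC."""
    from . import discrimination  # late import; discrimination is downstream

    settings = settings or AnalysisSettings()
    try:
        x, y = cohort.subset_complete(prom)
        fit = fit_logistic_mle(x, y)
        if settings.cov_source is CovSource.BOOTSTRAP:
            boot = bootstrap_covariance(x, y, B=settings.n_boot, seed=settings.seed)
            fit = replace(
                fit,
                cov=boot.cov,
                cov_source=CovSource.BOOTSTRAP,
                n_boot_requested=boot.n_requested,
                n_boot_converged=boot.n_converged,
            )
        curve = probability_curve(fit, prom, level=settings.level, scale=settings.band_scale)
        thresholds = find_thresholds(curve, cohort.p0, prom)
        risk = discrimination.risk_scores(x, prom)
        auc = discrimination.compute_auc(risk, y)
        ci = discrimination.auc_ci(risk, y, B=settings.n_boot, seed=settings.seed + 1)
        roc = discrimination.ROCResult(
            prom=prom.name,
            auc=auc,
            ci_lower=ci[0],
            ci_upper=ci[1],
            category=discrimination.categorize_auc(auc),
            n_pairs=int(y.sum()) * int((1 - y).sum()),
        )
    except (EstimationError, ValueError) as exc:
        raise EstimationError(f"{prom.name}: {exc}") from exc
    return PROMAnalysis(prom=prom.name, fit=fit, curve=curve, thresholds=thresholds, roc=roc)
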