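"""Independent oracles used by the test suite.

These deliberately avoid the package's estimation code paths: the logistic
oracle maximizes the log-likelihood by multiresolution grid search, the AUC
oracle enumerates every failure x success pair, and the ECDF oracle is a
plain sort-and-count.
"""

from __future__ import annotations

import numpy as np


def loglik(b0: float, b1: float, x: np.ndarray, y: np.ndarray) -> float:
    eta = b0 + b1 * x
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def grid_search_logistic(
    x, y, box: float = 10.0, final_step: float = 2.5e-4
) -> tuple[float, float]:
    """Maximize the logistic log-likelihood over [-box, box]^2 by coarse-to-fine
    grid search, refining down to a final grid spacing of `final_step`.

    The log-likelihood is concave, so re-centering a generous window around
    the running best cannot lose the maximizer. The final spacing sits well
    below the 2e-3 comparison tolerance because (b0, b1) are strongly
    correlated: a half-step quantization of b1 shifts b0's conditional
    optimum by roughly mean(x) * step/2.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    steps = [0.5, 0.1, 0.02, 0.004, 0.001, final_step]
    best = (0.0, 0.0)
    lo0, hi0 = -box, box
    lo1, hi1 = -box, box
    for prev, step in zip([None, *steps], steps):
        b0s = np.arange(lo0, hi0 + step / 2, step)
        b1s = np.arange(lo1, hi1 + step / 2, step)
        ll = np.array([[loglik(b0, b1, x, y) for b1 in b1s] for b0 in b0s])
        i0, i1 = np.unravel_index(np.argmax(ll), ll.shape)
        best = (float(b0s[i0]), float(b1s[i1]))
        window = 4 * (prev or step)  # wide enough to absorb ridge quantization
        lo0, hi0 = max(-box, best[0] - window), min(box, best[0] + window)
        lo1, hi1 = max(-box, best[1] - window), min(box, best[1] + window)
    return best


def brute_force_auc(scores, outcomes) -> float:
    """AUC by enumerating all failure x success pairs (half-credit for ties)."""
    x = np.asarray(scores, float)
    y = np.asarray(outcomes, float)
    f = x[y == 1.0]
    s = x[y == 0.0]
    conc = (f[:, None] > s[None, :]).sum()
    ties = (f[:, None] == s[None, :]).sum()
    return (conc + 0.5 * ties) / (len(f) * len(s))


def sort_and_count_ecdf(scores, outcomes):
    """Group-wise cumulative counts by direct counting at each unique score."""
    x = np.asarray(scores, float)
    y = np.asarray(outcomes, float)
    values = sorted(set(x.tolist()))
    cum_f = [int(((x <= v) & (y == 1.0)).sum()) for v in values]
    cum_s = [int(((x <= v) & (y == 0.0)).sum()) for v in values]
    prop = [(cf + cs) / len(x) for cf, cs in zip(cum_f, cum_s)]
    return values, cum_f, cum_s, prop
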