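"""Prize-response models: how prizes move valuations and go-decisions.

Two regressions are fitted separately for every indication x prize-phase
combination:

* improvement model — ordinary least squares of log10(valuation
  improvement) on log10(prize size).  Prizes always improve the
  developer's valuation, so the response is positive and, on log-log
  scale, close to linear with homogeneous scatter.

* P(go) model — logistic regression of the post-prize go-decision on
  log10(prize size), fitted only on projects that faced a no-decision
  without the prize.  It therefore models the *conditional* probability of
  turning a no-decision into a go-decision,

      ln[P(go) / (1 - P(go))] = b0 + b1 * log10(prize)

The logistic link is analytically invertible: the prize that hits a target
P(go) is 10^[(logit(target) - b0) / b1].

Prize sizes are in million USD throughout, matching the rest of the
package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy.optimize import minimize
from statsmodels.tools.sm_exceptions import (
    ConvergenceWarning,
    PerfectSeparationError,
    PerfectSeparationWarning,
)

__all__ = [
    "IncentiveResponseFit",
    "SeparationError",
    "fit_improvement",
    "fit_pgo",
    "predict_pgo",
    "solve_prize",
]

MIN_OBS = 30  # fits on fewer observations are flagged


class SeparationError(RuntimeError):
    """Raised when a logistic fit is degenerate (one outcome class only)."""


@dataclass(frozen=True)
class IncentiveResponseFit:
    """Fitted coefficients of one response model.

    ``beta0`` is the intercept and ``beta1`` the slope on log10(prize size
    in million USD).  ``max_p_value`` is the larger of the two coefficient
    p-values; ``flagged`` marks fits rescued from complete separation by a
    mild ridge penalty (their p-values are not trustworthy).
    """

    indication: str
    prize_phase: str
    model: str  # "improvement_loglog" | "pgo_logistic"
    beta0: float
    beta1: float
    n_obs: int
    max_p_value: float
    flagged: bool = False


def fit_improvement(
    samples: Sequence[tuple[float, float]],
    indication: str = "",
    prize_phase: str = "",
) -> IncentiveResponseFit:
    """OLS of log10(improvement) on log10(prize size).

    ``samples`` are (prize_size, improvement) pairs with improvement > 0.
    """
    if len(samples) < 3:
        raise ValueError(f"need at least 3 samples, got {len(samples)}")
    arr = np.asarray(samples, dtype=float)
    prize, imp = arr[:, 0], arr[:, 1]
    if np.any(prize <= 0):
        raise ValueError("prize sizes must be > 0")
    if np.any(imp <= 0):
        raise ValueError("improvements must be > 0 (prizes always improve value)")
    x = sm.add_constant(np.log10(prize))
    res = sm.OLS(np.log10(imp), x).fit()
    return IncentiveResponseFit(
        indication=indication,
        prize_phase=prize_phase,
        model="improvement_loglog",
        beta0=float(res.params[0]),
        beta1=float(res.params[1]),
        n_obs=len(samples),
        max_p_value=float(np.max(res.pvalues)),
        flagged=len(samples) < MIN_OBS,
    )


def _ridge_logit(x: np.ndarray, y: np.ndarray, alpha: float = 1.0) -> np.ndarray:
    """Mildly penalised logistic fit used when the MLE separates."""

    def negll(beta: np.ndarray) -> float:
        eta = x @ beta
        # log(1 + e^eta) - y*eta, numerically stable
        return float(
            np.sum(np.logaddexp(0.0, eta) - y * eta) + 0.5 * alpha * beta @ beta
        )

    res = minimize(negll, x0=np.zeros(x.shape[1]), method="BFGS")
    return res.x


def fit_pgo(
    samples: Sequence[tuple[float, bool]],
    indication: str = "",
    prize_phase: str = "",
) -> IncentiveResponseFit:
    """Logistic regression of go_with on log10(prize size).

    ``samples`` must come from projects that faced a no-decision without
    the prize; each pair is (prize_size, go_with).  Raises
    :class:`SeparationError` when only one outcome class is present.  On
    complete separation along the prize axis the fit is rescued with a
    mild ridge penalty and flagged.
    """
    if len(samples) < 3:
        raise ValueError(f"need at least 3 samples, got {len(samples)}")
    prize = np.asarray([s[0] for s in samples], dtype=float)
    y = np.asarray([bool(s[1]) for s in samples], dtype=float)
    if np.any(prize <= 0):
        raise ValueError("prize sizes must be > 0")
    if y.min() == y.max():
        raise SeparationError(
            f"all outcomes identical ({'go' if y[0] else 'no'}) — cannot fit"
        )
    x = sm.add_constant(np.log10(prize))

    flagged = len(samples) < MIN_OBS
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            warnings.simplefilter("error", category=PerfectSeparationWarning)
            warnings.simplefilter("error", category=ConvergenceWarning)
            res = sm.Logit(y, x).fit(disp=0)
        params = np.asarray(res.params, dtype=float)
        pmax = float(np.max(res.pvalues))
        if not res.mle_retvals.get("converged", True) or not np.all(np.isfinite(params)):
            raise PerfectSeparationError("non-converged logistic fit")
    except (PerfectSeparationError, Warning, np.linalg.LinAlgError, RuntimeError):
        params = _ridge_logit(x, y)
        pmax = float("nan")
        flagged = True

    return IncentiveResponseFit(
        indication=indication,
        prize_phase=prize_phase,
        model="pgo_logistic",
        beta0=float(params[0]),
        beta1=float(params[1]),
        n_obs=len(samples),
        max_p_value=pmax,
        flagged=flagged,
    )


def predict_pgo(fit: IncentiveResponseFit, prize_size: float) -> float:
    """Conditional go-probability at a prize size (million USD)."""
    if prize_size <= 0:
        raise ValueError("prize_size must be > 0")
    eta = fit.beta0 + fit.beta1 * np.log10(prize_size)
    return float(1.0 / (1.0 + np.exp(-eta)))


def solve_prize(fit: IncentiveResponseFit, target_pgo: float) -> float:
    """Prize size (million USD) at which the fitted model reaches a target
    conditional go-probability; the analytic inverse of the logistic."""
    if not (0.0 < target_pgo < 1.0):
        raise ValueError("target_pgo must be strictly inside (0, 1)")
    if fit.beta1 == 0:
        raise ValueError("flat response (beta1 = 0) cannot be inverted")
    logit = np.log(target_pgo / (1.0 - target_pgo))
    return float(10.0 ** ((logit - fit.beta0) / fit.beta1))
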