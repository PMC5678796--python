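"""GLM fit of the genotype covariate and the large-sample Wald z test.

Both families reduce to an intercept-plus-slope fit of a covariate that
takes at most three distinct values, so the logistic likelihood depends on
the data only through per-genotype-class counts of individuals and cases.
The fitter exploits this: it aggregates to class totals and runs Newton
iterations on the two-parameter grouped likelihood, which is exact and
orders of magnitude faster than a per-observation IRLS sweep (hundreds of
thousands of replicate fits are needed per study). The Gaussian family is
ordinary least squares via :func:`scipy.stats.linregress`.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy.special import expit
from scipy.stats import linregress, norm

__all__ = ["FitResult", "fit_glm", "wald_test"]

_MAX_ITER = 25       # IRLS-equivalent Newton step cap
_MAX_ABS_BETA = 40.0  # beyond this the MLE is effectively at infinity
_TOL = 1e-10


@dataclasses.dataclass(frozen=True)
class FitResult:
    """Slope estimate for one replicate.

    ``beta_hat`` is the log-OR (logistic) or mean shift (gaussian) per
    coded genotype unit; ``se`` comes from the observed information at
    the MLE; ``p_value = 2 * (1 - Phi(|z|))``. Non-converged fits carry
    NaN estimates and ``p_value = 1`` so they can never be detections.
    """

    beta_hat: float
    se: float
    z: float
    p_value: float
    converged: bool


_FAILED = FitResult(beta_hat=math.nan, se=math.nan, z=math.nan,
                    p_value=1.0, converged=False)


def _wald_from(beta: float, se: float) -> FitResult:
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se if se > 0 else math.copysign(math.inf, beta)
    if not math.isfinite(z):
        # se == 0 with beta != 0: exact fit, infinitely precise slope
        if se == 0.0 and beta != 0.0 and math.isfinite(beta):
            return FitResult(beta, 0.0, math.copysign(math.inf, beta),
                             0.0, True)
        return _FAILED
    return FitResult(beta, se, z, 2.0 * norm.sf(abs(z)), True)


def _neg_loglik(b0: float, b1: float, values: np.ndarray, counts: np.ndarray,
                cases: np.ndarray) -> float:
    eta = b0 + b1 * values
    # log(1 + e^eta) computed stably
    log1pexp = np.logaddexp(0.0, eta)
    return float((counts * log1pexp - cases * eta).sum())


def _fit_logistic_grouped(values: np.ndarray, counts: np.ndarray,
                          cases: np.ndarray) -> FitResult:
    """Newton-Raphson with step-halving on the grouped binomial likelihood."""
    total = counts.sum()
    ybar = cases.sum() / total
    b0 = math.log(ybar / (1.0 - ybar))  # ybar strictly inside (0,1) here
    b1 = 0.0
    nll = _neg_loglik(b0, b1, values, counts, cases)
    for _ in range(_MAX_ITER):
        mu = expit(b0 + b1 * values)
        resid = cases - counts * mu
        w = counts * mu * (1.0 - mu)
        info = np.array([[w.sum(), (w * values).sum()],
                         [(w * values).sum(), (w * values * values).sum()]])
        score = np.array([resid.sum(), (values * resid).sum()])
        try:
            delta = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            return _FAILED
        # step-halving keeps extreme-but-finite-MLE tables on track
        step = 1.0
        for _ in range(20):
            cand = _neg_loglik(b0 + step * delta[0], b1 + step * delta[1],
                               values, counts, cases)
            if cand <= nll + 1e-12:
                break
            step *= 0.5
        b0 += step * delta[0]
        b1 += step * delta[1]
        nll = _neg_loglik(b0, b1, values, counts, cases)
        if not (math.isfinite(b0) and math.isfinite(b1)):
            return _FAILED
        if max(abs(b0), abs(b1)) > _MAX_ABS_BETA:
            return _FAILED  # separation: MLE diverges
        if step * max(abs(delta[0]), abs(delta[1])) < _TOL:
            break
    else:
        return _FAILED
    mu = expit(b0 + b1 * values)
    w = counts * mu * (1.0 - mu)
    info = np.array([[w.sum(), (w * values).sum()],
                     [(w * values).sum(), (w * values * values).sum()]])
    det = info[0, 0] * info[1, 1] - info[0, 1] * info[1, 0]
    if det <= 0:
        return _FAILED
    se = math.sqrt(info[0, 0] / det)
    return _wald_from(b1, se)


def fit_glm(g_coded: np.ndarray, outcome: np.ndarray, family: str) -> FitResult:
    """Maximum-likelihood intercept+slope fit of ``outcome ~ g_coded``.

    ``family`` is ``"logistic"`` (binary outcome in {0, 1}) or
    ``"gaussian"`` (ordinary least squares). A monomorphic covariate or a
    constant outcome yields ``converged=False`` rather than an error, as
    does complete separation in the logistic family.
    """
    g = np.asarray(g_coded, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if g.shape != y.shape:
        raise ValueError("g_coded and outcome: length mismatch")
    if g.shape[0] < 2:
        raise ValueError("need at least 2 observations")
    if family not in ("logistic", "gaussian"):
        raise ValueError(f"family: unknown family {family!r}")

    if np.all(g == g[0]) or np.all(y == y[0]):
        return _FAILED  # slope unidentifiable / outcome degenerate

    if family == "logistic":
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("outcome: logistic family requires values in {0, 1}")
        values, inverse = np.unique(g, return_inverse=True)
        counts = np.bincount(inverse).astype(float)
        cases = np.bincount(inverse, weights=y)
        return _fit_logistic_grouped(values, counts, cases)

    res = linregress(g, y)
    if not (math.isfinite(res.slope) and math.isfinite(res.stderr)):
        return _FAILED
    return _wald_from(float(res.slope), float(res.stderr))


def wald_test(fit: FitResult, alpha: float) -> bool:
    """True when the fit converged and ``p_value < alpha`` (two-sided)."""
    return bool(fit.converged and fit.p_value < alpha)
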