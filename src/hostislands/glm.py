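"""Binomial GLM with logit link, fitted by iteratively reweighted least
squares, and the quantities the island analysis derives from it.

The model is logit(UP) = a·PA + b, where UP is the probability that a plant
family is utilized by a group and PA is the family's apparency.  From a fit we
derive:

* ``G = a²/VAR(a)`` — a Wald statistic against chi-square(1) for the slope,
* ``PA_0.5 = −b/a`` and ``PA_0.95 = (ln 19 − b)/a`` — the apparency at which
  the fitted utilization probability reaches 0.5 and 0.95,
* ``UP_0 = logistic(b)`` — the fitted probability for a vanishingly
  unapparent family (PA → 0).

Completely separated fits have no finite maximum-likelihood estimate; they
are flagged and every derived quantity refuses to compute from them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit
from scipy.stats import chi2

from .errors import DegenerateResponseError, SeparationError, ValidationError

#: |a·sd(PA)| beyond which the slope is treated as diverging (separation).
SEPARATION_SLOPE_LIMIT = 50.0
DEVIANCE_TOL = 1e-8
MAX_ITER = 200


@dataclass
class GLMFit:
    a: float          # slope, logit units per PA unit
    b: float          # intercept, logit units
    var_a: float
    var_b: float
    n: int
    deviance: float   # -2 log-likelihood
    converged: bool
    separated: bool


@dataclass
class DerivedQuantities:
    PA_05: float
    PA_095: float
    UP_0: float


def _deviance(y: np.ndarray, mu: np.ndarray) -> float:
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    return float(-2.0 * np.sum(y * np.log(mu) + (1 - y) * np.log1p(-mu)))


def fit_binomial_logit(pa, y, max_iter: int = MAX_ITER,
                       tol: float = DEVIANCE_TOL) -> GLMFit:
    """Maximum-likelihood (a, b) by IRLS with Newton steps on (slope, intercept).

    Starts from a=0, b=logit(mean(y)); converges when the deviance change
    drops below *tol*.  Variances come from the inverse observed information
    (identical to the expected information under the canonical logit link).
    """
    pa = np.asarray(pa, dtype=float)
    y = np.asarray(y, dtype=float)
    if pa.shape != y.shape or pa.ndim != 1 or pa.size < 2:
        raise ValidationError("pa and y must be equal-length vectors, n >= 2")
    if not np.all(np.isfinite(pa)):
        raise ValidationError("non-finite apparency value")
    if not np.all((y == 0) | (y == 1)):
        raise ValidationError("response must be binary 0/1")
    if y.min() == y.max():
        raise DegenerateResponseError(
            "response is constant (all 0 or all 1); logit fit undefined")

    n = pa.size
    x_mat = np.column_stack([pa, np.ones(n)])
    beta = np.array([0.0, float(logit(np.clip(y.mean(), 1e-6, 1 - 1e-6)))])
    dev = _deviance(y, expit(x_mat @ beta))
    converged = False
    for _ in range(max_iter):
        mu = expit(x_mat @ beta)
        w = np.clip(mu * (1 - mu), 1e-12, None)
        info = x_mat.T @ (w[:, None] * x_mat)
        score = x_mat.T @ (y - mu)
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            break
        # step-halving keeps the deviance non-increasing
        new_dev = None
        for _half in range(30):
            cand = beta + step
            cand_dev = _deviance(y, expit(x_mat @ cand))
            if cand_dev <= dev + 1e-12:
                new_dev = cand_dev
                beta = cand
                break
            step = step / 2.0
        if new_dev is None:
            break
        if abs(dev - new_dev) < tol:
            dev = new_dev
            converged = True
            break
        dev = new_dev

    mu = expit(x_mat @ beta)
    w = np.clip(mu * (1 - mu), 1e-12, None)
    info = x_mat.T @ (w[:, None] * x_mat)
    try:
        cov = np.linalg.inv(info)
        var_a, var_b = float(cov[0, 0]), float(cov[1, 1])
    except np.linalg.LinAlgError:
        var_a = var_b = float("inf")

    sd_pa = float(pa.std())
    perfect = dev < 1e-6
    separated = bool(abs(beta[0]) * sd_pa > SEPARATION_SLOPE_LIMIT or perfect)
    return GLMFit(a=float(beta[0]), b=float(beta[1]), var_a=var_a,
                  var_b=var_b, n=int(n), deviance=dev,
                  converged=converged and not separated, separated=separated)


def g_statistic(fit: GLMFit):
    """Wald slope test G = a²/VAR(a) against chi-square with 1 df."""
    if fit.separated:
        raise SeparationError(
            "separated fit: exclude this group rather than testing its slope")
    if not fit.var_a > 0:
        raise ValidationError("VAR(a) must be positive for the G statistic")
    g = fit.a ** 2 / fit.var_a
    return g, float(chi2.sf(g, df=1))


def derived_quantities(fit: GLMFit) -> DerivedQuantities:
    """Apparency thresholds PA_0.5, PA_0.95 and the zero-apparency UP_0."""
    if fit.separated:
        raise SeparationError("separated fit: derived quantities undefined")
    if fit.a == 0:
        raise ValidationError("slope a = 0: apparency thresholds undefined")
    pa_05 = -fit.b / fit.a
    pa_095 = (np.log(19.0) - fit.b) / fit.a   # logit(0.95) = ln 19
    up_0 = float(expit(fit.b))
    return DerivedQuantities(PA_05=float(pa_05), PA_095=float(pa_095),
                             UP_0=up_0)


def predict_up(fit: GLMFit, pa) -> float | np.ndarray:
    """Fitted utilization probability at apparency *pa*; strictly in (0, 1)."""
    if fit.separated:
        raise SeparationError("separated fit: predictions undefined")
    out = expit(fit.a * np.asarray(pa, dtype=float) + fit.b)
    return float(out) if np.isscalar(pa) or np.ndim(pa) == 0 else out
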