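"""Ordinary least squares and the cross-family / cross-group relationships
of the island analysis, plus the randomized binomial baseline.

Cross-family: the utilizer ratio UR against log10(apparency) and against
PD_min.  Cross-group: the fitted apparency thresholds (log10 PA_0.5 and
log10 PA_0.95), the zero-apparency probability UP_0, and the phylogenetic
signal D against host breadth HF (and UP_0 against log10 D).  The baseline
refits the same GLM to presence vectors drawn independently of apparency, so
any apparency effect in the real fits stands out against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import glm
from .errors import ValidationError
from .glm import DerivedQuantities, GLMFit
from .signal_d import DResult
from .tables import FamilySummary

BASELINE_PROBS = (0.1, 0.3, 0.5, 0.7, 0.9)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    p: float
    n: int
    degenerate: bool = False


@dataclass
class GroupSummary:
    """One utilization group's fitted pieces, ready for cross-group work."""

    group: str
    HF: int
    fit: GLMFit | None = None
    derived: DerivedQuantities | None = None
    d_result: DResult | None = None


def ols(x, y) -> RegressionResult:
    """Simple linear regression: slope, intercept, r² and two-sided slope p.

    Zero-variance x has no defined slope and raises; zero-variance y returns
    the degenerate flat fit (slope 0, r² 0, p 1) with a flag.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValidationError("x and y must be equal-length vectors, n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("non-finite value in regression input")
    if np.ptp(x) == 0:
        raise ValidationError("zero-variance x: slope undefined")
    if np.ptp(y) == 0:
        return RegressionResult(0.0, float(y[0]), 0.0, 1.0, x.size,
                                degenerate=True)
    res = stats.linregress(x, y)
    return RegressionResult(float(res.slope), float(res.intercept),
                            float(res.rvalue ** 2), float(res.pvalue),
                            int(x.size))


def family_relationships(summaries: list) -> dict:
    """UR against log10(apparency) and UR against PD_min across families."""
    if len(summaries) < 3:
        raise ValidationError("need at least 3 families")
    ur = np.array([s.UR for s in summaries])
    pa = np.array([s.apparency for s in summaries])
    pdm = np.array([s.PD_min for s in summaries])
    if np.any(pa <= 0):
        raise ValidationError("apparency must be positive for log10")
    return {
        "UR_vs_log10_apparency": ols(np.log10(pa), ur),
        "UR_vs_PD_min": ols(pdm, ur),
    }


def group_relationships(summaries: list) -> tuple[dict, list]:
    """The five cross-group regressions; returns (results, exclusion log).

    Groups with separated, non-converged or non-positive-slope fits are
    excluded from every regression; log-scale regressions additionally drop
    groups whose threshold (or D) is not positive.  Every exclusion is
    recorded as ``(group, regression, reason)``.
    """
    exclusions: list = []
    valid: list = []
    for s in summaries:
        if s.fit is None or s.derived is None:
            exclusions.append((s.group, "*", "no fit"))
        elif s.fit.separated:
            exclusions.append((s.group, "*", "separated fit"))
        elif not s.fit.converged:
            exclusions.append((s.group, "*", "fit did not converge"))
        elif s.fit.a <= 0:
            exclusions.append((s.group, "*", "non-positive slope"))
        else:
            valid.append(s)
    if len(valid) < 3:
        raise ValidationError(
            f"fewer than 3 groups with valid fits ({len(valid)})")

    def _screened(name, xs, ys, pred, reason):
        xs_ok, ys_ok = [], []
        for s, xv, yv in zip(valid, xs, ys):
            if pred(s):
                xs_ok.append(xv)
                ys_ok.append(yv)
            else:
                exclusions.append((s.group, name, reason))
        if len(xs_ok) < 3:
            exclusions.append(("*", name, "fewer than 3 usable groups"))
            return None
        try:
            return ols(np.array(xs_ok), np.array(ys_ok))
        except ValidationError as exc:
            exclusions.append(("*", name, str(exc)))
            return None

    hf = [float(s.HF) for s in valid]
    results = {
        "log10_PA05_vs_HF": _screened(
            "log10_PA05_vs_HF", hf,
            [np.log10(s.derived.PA_05) if s.derived.PA_05 > 0 else np.nan
             for s in valid],
            lambda s: s.derived.PA_05 > 0, "non-positive PA_0.5"),
        "log10_PA095_vs_HF": _screened(
            "log10_PA095_vs_HF", hf,
            [np.log10(s.derived.PA_095) if s.derived.PA_095 > 0 else np.nan
             for s in valid],
            lambda s: s.derived.PA_095 > 0, "non-positive PA_0.95"),
        "UP0_vs_HF": _screened(
            "UP0_vs_HF", hf, [s.derived.UP_0 for s in valid],
            lambda s: True, ""),
        "D_vs_log10_HF": _screened(
            "D_vs_log10_HF", list(np.log10(hf)),
            [s.d_result.D if s.d_result else np.nan for s in valid],
            lambda s: s.d_result is not None, "no D result"),
        "UP0_vs_log10_D": _screened(
            "UP0_vs_log10_D",
            [np.log10(s.d_result.D) if s.d_result and s.d_result.D > 0
             else np.nan for s in valid],
            [s.derived.UP_0 for s in valid],
            lambda s: s.d_result is not None and s.d_result.D > 0,
            "non-positive D"),
    }
    return results, exclusions


def randomized_baseline(pa, probs=BASELINE_PROBS, n_reps: int = 1000,
                        seed: int = 0) -> pd.DataFrame:
    """Refit the apparency GLM to presence drawn independently of apparency.

    For each success probability *p* and replicate, a Bernoulli(p) presence
    vector is drawn i.i.d. over families and the logit model is refitted.
    Since the truth has zero slope, the fitted UP_0 should track *p* and the
    thresholds should be uninformative — the contrast against real fits.
    Degenerate and separated replicates are kept in the table (flagged) so
    summaries can exclude them explicitly.
    """
    pa = np.asarray(pa, dtype=float)
    if np.ptp(pa) == 0:
        raise ValidationError("apparency vector is constant")
    rng = np.random.default_rng(seed)
    rows = []
    for p in probs:
        for rep in range(n_reps):
            y = (rng.random(pa.size) < p).astype(float)
            row = {"p": p, "rep": rep, "a": np.nan, "b": np.nan,
                   "UP_0": np.nan, "PA_05": np.nan, "PA_095": np.nan,
                   "separated": False, "degenerate": False}
            if y.min() == y.max():
                row["degenerate"] = True
            else:
                fit = glm.fit_binomial_logit(pa, y)
                row["a"], row["b"] = fit.a, fit.b
                row["separated"] = fit.separated
                if not fit.separated and fit.a != 0:
                    dq = glm.derived_quantities(fit)
                    row.update(UP_0=dq.UP_0, PA_05=dq.PA_05,
                               PA_095=dq.PA_095)
            rows.append(row)
    return pd.DataFrame(rows)


def summarize_baseline(baseline: pd.DataFrame) -> pd.DataFrame:
    """Per-p means over usable replicates (separated/degenerate excluded)."""
    ok = baseline[~(baseline["separated"] | baseline["degenerate"])]
    return ok.groupby("p").agg(
        mean_a=("a", "mean"),
        mean_UP_0=("UP_0", "mean"),
        n_used=("rep", "size"),
    ).reset_index()
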