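"""Clonogenic activity: point estimate and confidence intervals.

The clonogenic activity ``a`` is the number of cells that must be seeded per
well so that on average one clonogenically active cell arises (lambda = 1),
which leaves a fraction ``1/e`` (about 37%) of wells without growth.  On the
link scale this is the root of the fitted line:

    a = exp(-alpha / b) = p**(-1/b).

Two interval methods are provided:

* ``band_inversion`` (the default): the S values at which the link-scale
  confidence band of the fit crosses zero — a Fieller-type interval obtained
  in closed form as the roots of a quadratic in ``ln S``.  When the band
  fails to re-cross the threshold on one side (slope not significantly
  different from zero), that bound is reported unbounded with a warning.
* ``delta``: first-order Taylor error propagation of ``ln a = -alpha/b``.

Only when growth is linear (``b = 1``) is ``1/a`` interpretable as an active
cell frequency; ``capacity_percent = 100/a`` is reported as a convenience
readout with that caveat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import LDAExperiment, pool_replicates
from .exceptions import (
    EstimationRefusedError,
    InputError,
    UnboundedIntervalWarning,
)
from .model import LDAResults, LimitingDilutionModel

__all__ = ["ActivityEstimate", "clonogenic_activity", "activity_table"]


@dataclass(frozen=True)
class ActivityEstimate:
    """Clonogenic activity a (cells/well) with a confidence interval.

    ``ci = (lower, upper)``; the upper bound may be ``inf`` and the lower
    bound ``0.0`` when the confidence band never crosses the 37% threshold on
    that side.  ``capacity_percent = 100/a``.
    """

    a: float
    ci: tuple[float, float]
    level: float
    method: str
    capacity_percent: float
    b: float

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise InputError(f"activity must be positive, got {self.a}")


def _band_inversion_interval(fit: LDAResults, level: float) -> tuple[float, float]:
    """Roots in x = ln S of (alpha + b x)^2 = z^2 Var(alpha + b x).

    The set of x where zero lies inside the link-scale band is bounded by the
    roots of the quadratic A x^2 + B x + C with

        A = b^2 - z^2 Var(b),  B = 2 (alpha b - z^2 Cov(alpha, b)),
        C = alpha^2 - z^2 Var(alpha).

    The interval on the S scale is the exponentiated root pair bracketing
    ``ln a``; a missing crossing on a side leaves that bound unbounded.
    """
    z = stats.norm.ppf(0.5 + level / 2.0)
    alpha, b = fit.alpha, fit.b
    va = fit.cov_params[0, 0]
    if fit.slope_fixed:
        vb, cab = 0.0, 0.0
    else:
        vb = fit.cov_params[1, 1]
        cab = fit.cov_params[0, 1]
    ln_a = -alpha / b

    A = b * b - z * z * vb
    B = 2.0 * (alpha * b - z * z * cab)
    C = alpha * alpha - z * z * va

    if A == 0.0:
        roots = np.array([-C / B]) if B != 0.0 else np.array([])
    else:
        disc = B * B - 4.0 * A * C
        if disc < 0.0:
            roots = np.array([])
        else:
            sq = np.sqrt(disc)
            roots = np.sort(np.array([(-B - sq), (-B + sq)]) / (2.0 * A))

    lower_roots = roots[roots < ln_a]
    upper_roots = roots[roots > ln_a]
    if lower_roots.size:
        lo = float(np.exp(lower_roots.max()))
    else:
        warnings.warn(
            "confidence band does not cross the 37% threshold below the "
            "estimate; lower activity bound reported as 0",
            UnboundedIntervalWarning,
            stacklevel=3,
        )
        lo = 0.0
    if upper_roots.size:
        hi = float(np.exp(upper_roots.min()))
    else:
        warnings.warn(
            "confidence band does not cross the 37% threshold above the "
            "estimate; upper activity bound reported as unbounded",
            UnboundedIntervalWarning,
            stacklevel=3,
        )
        hi = float("inf")
    return lo, hi


def _delta_interval(fit: LDAResults, level: float) -> tuple[float, float]:
    """First-order error propagation for ln a = -alpha/b."""
    z = stats.norm.ppf(0.5 + level / 2.0)
    alpha, b = fit.alpha, fit.b
    va = fit.cov_params[0, 0]
    if fit.slope_fixed:
        vb, cab = 0.0, 0.0
    else:
        vb = fit.cov_params[1, 1]
        cab = fit.cov_params[0, 1]
    var_ln_a = va / b**2 + alpha**2 * vb / b**4 - 2.0 * alpha * cab / b**3
    sd = np.sqrt(max(var_ln_a, 0.0))
    a = np.exp(-alpha / b)
    return float(a * np.exp(-z * sd)), float(a * np.exp(z * sd))


def clonogenic_activity(
    fit: LDAResults, level: float = 0.95, method: str = "band_inversion"
) -> ActivityEstimate:
    """Clonogenic activity a = exp(-alpha/b) with a confidence interval.

    Parameters
    ----------
    fit : LDAResults
        A converged model fit with positive slope.
    level : float
        Confidence level, e.g. 0.95, or 0.835 when the interval feeds the
        survival-fraction combination rule.
    method : {"band_inversion", "delta"}
        Fieller-type inversion of the link-scale confidence band (default),
        or first-order Taylor error propagation.
    """
    if not 0 < level < 1:
        raise InputError(f"level must be in (0, 1), got {level}")
    if not fit.converged:
        raise EstimationRefusedError(
            "activity requested from a non-converged fit; estimates may lie "
            "on a likelihood boundary"
        )
    if fit.b <= 0:
        raise EstimationRefusedError(
            f"estimated slope b = {fit.b:.4g} is not positive; the activity "
            f"a = exp(-alpha/b) is undefined"
        )
    if method == "band_inversion":
        ci = _band_inversion_interval(fit, level)
    elif method == "delta":
        ci = _delta_interval(fit, level)
    else:
        raise InputError(f"unknown method {method!r}")
    a = float(np.exp(-fit.alpha / fit.b))
    return ActivityEstimate(
        a=a,
        ci=ci,
        level=level,
        method=method,
        capacity_percent=100.0 / a,
        b=fit.b,
    )


def activity_table(
    experiment: LDAExperiment,
    mode: str = "pooled",
    level: float = 0.95,
    method: str = "band_inversion",
) -> pd.DataFrame:
    """Activity estimates for every treatment (and replicate) of an experiment.

    ``mode="pooled"`` sums wells across biological replicates before fitting
    (one row per treatment); ``mode="per_replicate"`` fits each replicate
    separately.  Conditions where not a single well shows growth are reported
    with ``refused_reason`` set rather than silently dropped.
    """
    if mode not in ("pooled", "per_replicate"):
        raise InputError(f"mode must be 'pooled' or 'per_replicate', got {mode!r}")
    rows = []
    for treatment in experiment.treatments:
        if mode == "pooled":
            groups = [pool_replicates(experiment.groups_for(treatment))]
        else:
            groups = experiment.groups_for(treatment)
        for group in groups:
            row = {
                "treatment": treatment,
                "replicate": group.replicate,
                "a": np.nan,
                "ci_lower": np.nan,
                "ci_upper": np.nan,
                "level": level,
                "method": method,
                "capacity_percent": np.nan,
                "b": np.nan,
                "refused_reason": "",
            }
            try:
                fit = LimitingDilutionModel(group).fit()
                est = clonogenic_activity(fit, level=level, method=method)
            except (EstimationRefusedError, InputError) as exc:
                row["refused_reason"] = str(exc)
            else:
                row.update(
                    a=est.a,
                    ci_lower=est.ci[0],
                    ci_upper=est.ci[1],
                    capacity_percent=est.capacity_percent,
                    b=est.b,
                )
            rows.append(row)
    return pd.DataFrame(rows)
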