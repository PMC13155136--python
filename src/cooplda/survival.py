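"""Survival fractions relative to an untreated reference.

The surviving fraction after a treatment is the ratio of clonogenic
activities

    SF_t = a_0 / a_t = exp(alpha_t / b_t - alpha_0 / b_0),

i.e. the factor by which the number of cells needed for one active cell per
well (37% failure rate) has grown under treatment.  Its 95% confidence
interval is approximated by combining the 83.5% confidence intervals of the
two activities:

    CI95(SF) = (a0_lb / at_ub,  a0_ub / at_lb),

a standard construction for ratios whose component intervals are
approximately independent.

Replicate handling follows two explicit modes: ``pooled`` sums wells across
biological replicates before fitting, while ``per_replicate`` computes the
survival fraction within each replicate (against its own reference fit) and
summarizes by mean, standard error of the mean, and a Student-t interval.
:func:`binomial_expectation_range` quantifies the intrinsic binomial
stochasticity of a well count, the diagnostic that guides the choice
between the two modes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import LDAExperiment, pool_replicates
from .exceptions import EstimationRefusedError, InputError, UnboundedIntervalWarning
from .model import LDAResults, LimitingDilutionModel
from .activity import clonogenic_activity

__all__ = [
    "SurvivalFraction",
    "survival_fraction",
    "survival_table",
    "binomial_expectation_range",
    "SF_COMPONENT_LEVEL",
]

#: Component activity-CI level whose combination approximates a 95% SF CI.
SF_COMPONENT_LEVEL = 0.835


@dataclass(frozen=True)
class SurvivalFraction:
    """Survival fraction of a treatment versus the reference, with 95% CI."""

    treatment: str
    reference: str
    sf: float
    ci95: tuple[float, float]
    mode: str = "pooled"
    per_replicate_values: tuple[float, ...] | None = None
    sem: float | None = None


def survival_fraction(
    fit_ref: LDAResults,
    fit_treat: LDAResults,
    component_level: float = SF_COMPONENT_LEVEL,
    method: str = "band_inversion",
) -> SurvivalFraction:
    """SF = a_0 / a_t from two fits, with the combined-interval 95% CI.

    Both fits must have converged; the treated condition must show growth in
    at least one well (otherwise its activity, and hence the SF, is not
    estimable).  An unbounded component activity bound propagates to an
    unbounded (or zero) SF bound with a warning.
    """
    est_ref = clonogenic_activity(fit_ref, level=component_level, method=method)
    est_treat = clonogenic_activity(fit_treat, level=component_level, method=method)
    sf = float(np.exp(fit_treat.alpha / fit_treat.b - fit_ref.alpha / fit_ref.b))
    lo, hi = combine_activity_cis(est_ref.ci, est_treat.ci)
    return SurvivalFraction(
        treatment=fit_treat.group.treatment,
        reference=fit_ref.group.treatment,
        sf=sf,
        ci95=(lo, hi),
    )


def combine_activity_cis(
    ci_ref: tuple[float, float], ci_treat: tuple[float, float]
) -> tuple[float, float]:
    """95% SF interval (a0_lb/at_ub, a0_ub/at_lb) from 83.5% activity CIs."""
    a0_lb, a0_ub = ci_ref
    at_lb, at_ub = ci_treat
    if not np.isfinite(at_ub) or not np.isfinite(a0_ub) or at_lb <= 0 or a0_lb <= 0:
        warnings.warn(
            "an unbounded activity bound propagates to an unbounded or zero "
            "survival-fraction bound",
            UnboundedIntervalWarning,
            stacklevel=3,
        )
    lo = a0_lb / at_ub if at_ub > 0 else float("inf")
    hi = a0_ub / at_lb if at_lb > 0 else float("inf")
    return float(lo), float(hi)


def survival_table(
    experiment: LDAExperiment,
    mode: str = "pooled",
    component_level: float = SF_COMPONENT_LEVEL,
    method: str = "band_inversion",
) -> pd.DataFrame:
    """Survival fractions for every treatment of an experiment.

    pooled
        Wells are summed across replicates; one SF per treatment from the
        pooled reference and treated fits; CI by the 83.5% combination rule.
    per_replicate
        The SF is computed within each biological replicate against that
        replicate's own reference fit, then summarized as mean, SEM and a
        Student-t 95% interval with ``replicates - 1`` degrees of freedom.

    The reference treatment's own row carries ``sf = 1`` exactly.  Treated
    conditions whose activity is not estimable are reported with
    ``refused_reason`` set.  A non-estimable reference is a hard error.
    """
    if mode not in ("pooled", "per_replicate"):
        raise InputError(f"mode must be 'pooled' or 'per_replicate', got {mode!r}")
    ref_label = experiment.reference_treatment
    rows = []
    if mode == "pooled":
        try:
            fit_ref = LimitingDilutionModel(
                pool_replicates(experiment.groups_for(ref_label))
            ).fit()
            clonogenic_activity(fit_ref, level=component_level, method=method)
        except (EstimationRefusedError, InputError) as exc:
            raise EstimationRefusedError(
                f"reference treatment {ref_label!r} is not estimable: {exc}"
            ) from exc
        for treatment in experiment.treatments:
            row = _blank_row(treatment, ref_label, mode)
            if treatment == ref_label:
                est = clonogenic_activity(fit_ref, level=component_level, method=method)
                row.update(sf=1.0, ci95_lower=est.ci[0] / est.ci[1],
                           ci95_upper=est.ci[1] / est.ci[0], n_replicates=len(
                               experiment.groups_for(treatment)))
                rows.append(row)
                continue
            try:
                fit_t = LimitingDilutionModel(
                    pool_replicates(experiment.groups_for(treatment))
                ).fit()
                res = survival_fraction(fit_ref, fit_t, component_level, method)
            except (EstimationRefusedError, InputError) as exc:
                row["refused_reason"] = str(exc)
            else:
                row.update(sf=res.sf, ci95_lower=res.ci95[0], ci95_upper=res.ci95[1],
                           n_replicates=len(experiment.groups_for(treatment)))
            rows.append(row)
        return pd.DataFrame(rows)

    # per_replicate: SF within each replicate, then mean / SEM / t interval
    ref_fits: dict[str, LDAResults] = {}
    for g in experiment.groups_for(ref_label):
        try:
            ref_fits[g.replicate] = LimitingDilutionModel(g).fit()
        except (EstimationRefusedError, InputError):
            continue
    if not ref_fits:
        raise EstimationRefusedError(
            f"reference treatment {ref_label!r} is not estimable in any replicate"
        )
    for treatment in experiment.treatments:
        row = _blank_row(treatment, ref_label, mode)
        values = []
        for g in experiment.groups_for(treatment):
            if g.replicate not in ref_fits:
                continue
            try:
                fit_t = LimitingDilutionModel(g).fit()
                res = survival_fraction(ref_fits[g.replicate], fit_t,
                                        component_level, method)
            except (EstimationRefusedError, InputError):
                continue
            values.append(res.sf)
        if not values:
            row["refused_reason"] = (
                "survival fraction not estimable in any replicate"
            )
            rows.append(row)
            continue
        r = len(values)
        mean = float(np.mean(values))
        sem = float(np.std(values, ddof=1) / np.sqrt(r)) if r > 1 else float("nan")
        if r > 1:
            tq = stats.t.ppf(0.975, df=r - 1)
            ci = (mean - tq * sem, mean + tq * sem)
        else:
            ci = (float("nan"), float("nan"))
        row.update(
            sf=mean, ci95_lower=ci[0], ci95_upper=ci[1], n_replicates=r, sem=sem,
            per_replicate_values=";".join(f"{v:.6g}" for v in values),
        )
        rows.append(row)
    return pd.DataFrame(rows)


def _blank_row(treatment: str, reference: str, mode: str) -> dict:
    return {
        "treatment": treatment,
        "reference": reference,
        "sf": np.nan,
        "ci95_lower": np.nan,
        "ci95_upper": np.nan,
        "mode": mode,
        "n_replicates": 0,
        "sem": np.nan,
        "per_replicate_values": "",
        "refused_reason": "",
    }


def binomial_expectation_range(
    n: int, p: float, level: float = 0.95
) -> tuple[int, int, tuple[float, float]]:
    """Equal-tail expectation range of a Binomial(n, p) well count.

    Returns ``(lo, hi, (ln(lo/n), ln(hi/n)))`` where ``lo`` and ``hi`` are
    the smallest counts whose exact cumulative probability reaches
    ``(1-level)/2`` and ``1-(1-level)/2``.  This quantifies the intrinsic
    stochasticity of the number of non-responding wells: for 12 wells with
    failure probability 1/3, the 95% range is 1 to 7 negative wells, about
    -2.5 to -0.5 on the ln(mu) scale.  A zero lower count maps to ``-inf``.
    """
    if int(n) != n or n < 1:
        raise InputError(f"n must be a positive integer, got {n!r}")
    if not 0 <= p <= 1:
        raise InputError(f"p must be in [0, 1], got {p!r}")
    if not 0 < level < 1:
        raise InputError(f"level must be in (0, 1), got {level!r}")
    n = int(n)
    tail = (1.0 - level) / 2.0
    # exact CDF by cumulative pmf summation
    k = np.arange(n + 1)
    cdf = np.cumsum(stats.binom.pmf(k, n, p))
    cdf = np.minimum(cdf, 1.0)
    lo = int(k[np.searchsorted(cdf, tail, side="left")])
    # smallest k with CDF(k) >= tail: searchsorted gives first index where
    # cdf >= tail since cdf is nondecreasing
    while cdf[lo] < tail and lo < n:
        lo += 1
    hi = int(np.argmax(cdf >= 1.0 - tail))
    ln_lo = float(np.log(lo / n)) if lo > 0 else float("-inf")
    ln_hi = float(np.log(hi / n)) if hi > 0 else float("-inf")
    return lo, hi, (ln_lo, ln_hi)
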