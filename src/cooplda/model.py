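"""Power-law binomial model of clonogenic growth in limiting dilution assays.

For a well seeded with an expected ``S`` cells, the number of clonogenically
active cells is modelled as Poisson with mean

    lambda = p * S**b,

a power-law generalization of the classical single-hit Poisson model
(``b = 1``).  The probability that a well shows no growth is therefore
``mu = exp(-lambda)``, and with ``alpha = ln p`` the model is linear on the
log-log link scale:

    ln(-ln mu) = alpha + b * ln S.

Counts of negative wells ``Y ~ Binomial(n, mu)`` at each dilution make this a
binomial GLM with log-log link.  ``b > 1`` indicates cooperative and
``0 < b < 1`` competitive clonogenic growth.

:class:`LimitingDilutionModel` holds the data and likelihood machinery;
:meth:`LimitingDilutionModel.fit` runs Fisher-scoring IRLS and returns a
:class:`LDAResults` carrying the estimates, their covariance (inverse
expected Fisher information at the optimum), deviance, AIC and prediction /
summary methods.  :func:`compare_models` performs the likelihood-ratio test
of the free-slope model against the nested fixed-slope (``b = 1``) model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import special, stats

from .data import AssayGroup
from .exceptions import ConvergenceWarning, EstimationRefusedError, InputError

__all__ = [
    "LimitingDilutionModel",
    "LDAResults",
    "ModelComparison",
    "fit_loglog_glm",
    "predict_failure_fraction",
    "compare_models",
    "fit_summary_table",
]

#: Convergence tolerance on the infinity norm of the score vector.
SCORE_TOL = 1e-8
#: Maximum Fisher-scoring iterations; the problems are tiny and well
#: conditioned, so this is generous.
MAX_ITER = 100
#: Link-scale values are clipped to this range during iteration to keep the
#: exponentials finite when the likelihood is maximized at a boundary.
ETA_CLIP = 30.0


def _mu_terms(eta: np.ndarray):
    """Return (t, mu, one_minus_mu) for eta, with t = exp(eta) = lambda."""
    t = np.exp(np.clip(eta, -ETA_CLIP, ETA_CLIP))
    mu = np.exp(-t)
    one_minus = -np.expm1(-t)  # accurate for small t where mu -> 1
    return t, mu, one_minus


class LimitingDilutionModel:
    """Binomial GLM of negative-well counts with log-log link.

    Parameters
    ----------
    group : AssayGroup
        Observations for one treatment condition (optionally pooled over
        biological replicates).
    slope_fixed : bool
        If True, fix ``b = 1`` (the classical single-hit Poisson model) and
        estimate the intercept only, with ``ln S`` as an offset.
    """

    def __init__(self, group: AssayGroup, slope_fixed: bool = False):
        self.group = group
        self.slope_fixed = bool(slope_fixed)
        self.S = group.cells_per_well
        self.n = group.n_wells.astype(float)
        self.y = group.n_negative.astype(float)
        self.logS = np.log(self.S)

        if group.all_negative:
            raise EstimationRefusedError(
                f"no clonogenic growth observed in any well of treatment "
                f"{group.treatment!r} (replicate {group.replicate!r}); "
                f"the clonogenic activity is not estimable"
            )
        n_distinct = np.unique(np.round(self.logS, 12)).size
        self.n_params = 1 if self.slope_fixed else 2
        if n_distinct < self.n_params:
            raise InputError(
                f"need at least {self.n_params} distinct dilutions for "
                f"{'fixed' if self.slope_fixed else 'free'}-slope fitting, "
                f"got {n_distinct}"
            )
        if self.slope_fixed:
            self.exog = np.ones((len(self.S), 1))
            self.offset = self.logS
        else:
            self.exog = np.column_stack([np.ones_like(self.logS), self.logS])
            self.offset = np.zeros_like(self.logS)

        self._ll_const = float(np.sum(special.gammaln(self.n + 1)
                                      - special.gammaln(self.y + 1)
                                      - special.gammaln(self.n - self.y + 1)))

    # -- likelihood machinery -------------------------------------------------

    def linear_predictor(self, params: np.ndarray) -> np.ndarray:
        return self.offset + self.exog @ np.asarray(params, dtype=float)

    def loglike(self, params: np.ndarray) -> float:
        """Binomial log-likelihood at (alpha[, b])."""
        t, mu, one_minus = _mu_terms(self.linear_predictor(params))
        with np.errstate(divide="ignore", invalid="ignore"):
            term_fail = np.where(self.y > 0, self.y * (-t), 0.0)
            term_grow = np.where(
                self.n - self.y > 0, (self.n - self.y) * np.log(one_minus), 0.0
            )
        return self._ll_const + float(np.sum(term_fail + term_grow))

    def score(self, params: np.ndarray) -> np.ndarray:
        """Gradient of the log-likelihood with respect to the parameters."""
        t, mu, one_minus = _mu_terms(self.linear_predictor(params))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(one_minus > 0, mu / one_minus, 0.0)
        u = -self.y * t + (self.n - self.y) * t * ratio
        return self.exog.T @ u

    def information(self, params: np.ndarray) -> np.ndarray:
        """Expected (Fisher) information matrix at the parameters."""
        t, mu, one_minus = _mu_terms(self.linear_predictor(params))
        with np.errstate(divide="ignore", invalid="ignore"):
            w = np.where(one_minus > 0, self.n * t * t * mu / one_minus, 0.0)
        return (self.exog * w[:, None]).T @ self.exog

    def _start_params(self) -> np.ndarray:
        """Initial values from least squares on link-transformed interior points."""
        interior = (self.y > 0) & (self.y < self.n)
        if interior.sum() >= 2:
            z = np.log(-np.log(self.y[interior] / self.n[interior]))
            x = self.logS[interior]
            if np.ptp(x) > 0:
                b0 = float(np.polyfit(x, z, 1)[0])
                b0 = min(max(b0, 0.05), 20.0)
                a0 = float(np.mean(z) - b0 * np.mean(x))
            else:
                a0, b0 = float(np.mean(z)) - np.mean(x), 1.0
        elif interior.sum() == 1:
            z = float(np.log(-np.log(self.y[interior][0] / self.n[interior][0])))
            a0, b0 = z - float(self.logS[interior][0]), 1.0
        else:
            a0, b0 = 0.0, 1.0
        return np.array([a0]) if self.slope_fixed else np.array([a0, b0])

    def fit(self, start_params=None) -> "LDAResults":
        """Maximize the likelihood by Fisher scoring with step halving.

        Returns an :class:`LDAResults`; if the score tolerance is not met
        within the iteration cap (e.g. quasi-separation when every well grows
        at every dilution) the result is flagged ``converged=False`` and a
        :class:`ConvergenceWarning` is emitted rather than raising.
        """
        beta = np.asarray(start_params, dtype=float) if start_params is not None \
            else self._start_params()
        ll = self.loglike(beta)
        converged = False
        n_iter = 0
        for n_iter in range(1, MAX_ITER + 1):
            s = self.score(beta)
            if np.max(np.abs(s)) < SCORE_TOL:
                converged = True
                break
            info = self.information(beta)
            try:
                step = np.linalg.solve(info, s)
            except np.linalg.LinAlgError:
                step = s / (np.trace(info) / len(beta) + 1e-12)
            # step halving: never accept a decrease in log-likelihood
            scale = 1.0
            for _ in range(40):
                cand = beta + scale * step
                ll_cand = self.loglike(cand)
                if ll_cand >= ll - 1e-12:
                    break
                scale *= 0.5
            else:
                break
            if abs(ll_cand - ll) < 1e-14 and np.max(np.abs(s)) < 1e-5:
                beta, ll = cand, ll_cand
                converged = True
                break
            beta, ll = cand, ll_cand
        # Boundary diagnostic: the smallest fitted lambda over the observed
        # dilutions is numerically 0 (the model claims certain failure at a
        # dilution) or so large that even the most dilute step has failure
        # probability below 1e-8 (certain growth everywhere).  Either only
        # happens on a quasi-separation ridge where the likelihood increases
        # toward infinite |parameters|; the gradient underflows on the ridge,
        # so the score test alone would mislabel such fits as converged.
        lam_min = float(np.exp(np.min(self.linear_predictor(beta))))
        if converged and (lam_min < 1e-8 or lam_min > -np.log(1e-8)):
            converged = False
        if not converged:
            warnings.warn(
                f"fit for treatment {self.group.treatment!r} did not reach the "
                f"score tolerance after {n_iter} iterations (score "
                f"{np.max(np.abs(self.score(beta))):.3g}); estimates may lie on "
                f"a likelihood boundary",
                ConvergenceWarning,
                stacklevel=2,
            )
        info = self.information(beta)
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            cov = np.full((self.n_params, self.n_params), np.nan)
        return LDAResults(
            model=self,
            params=beta,
            cov_params=cov,
            llf=ll,
            converged=converged,
            n_iter=n_iter,
        )

    # -- saturated reference --------------------------------------------------

    def loglike_saturated(self) -> float:
        """Log-likelihood of the saturated model (mu_i = Y_i / n_i)."""
        frac = self.y / self.n
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = np.where(self.y > 0, self.y * np.log(frac), 0.0)
            t2 = np.where(self.n - self.y > 0, (self.n - self.y) * np.log1p(-frac), 0.0)
        return self._ll_const + float(np.sum(t1 + t2))


@dataclass
class LDAResults:
    """Fitted power-law clonogenic growth model.

    Attributes
    ----------
    params : ndarray
        ``(alpha, b)`` for the free-slope model, ``(alpha,)`` when the slope
        is fixed at 1.  ``alpha = ln p`` is the intercept on the log-log link
        scale.
    cov_params : ndarray
        Inverse expected Fisher information at the optimum.
    llf, deviance, aic : float
        Log-likelihood, deviance against the saturated model, and Akaike
        information criterion ``-2 llf + 2 k``.
    """

    model: LimitingDilutionModel
    params: np.ndarray
    cov_params: np.ndarray
    llf: float
    converged: bool
    n_iter: int

    @property
    def group(self) -> AssayGroup:
        return self.model.group

    @property
    def slope_fixed(self) -> bool:
        return self.model.slope_fixed

    @property
    def alpha(self) -> float:
        return float(self.params[0])

    @property
    def b(self) -> float:
        return 1.0 if self.slope_fixed else float(self.params[1])

    @property
    def n_params(self) -> int:
        return self.model.n_params

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    @property
    def deviance(self) -> float:
        return max(2.0 * (self.model.loglike_saturated() - self.llf), 0.0)

    @property
    def aic(self) -> float:
        return -2.0 * self.llf + 2.0 * self.n_params

    # -- link-scale variance and prediction -----------------------------------

    def link_variance(self, logS) -> np.ndarray:
        """Variance of the estimated linear predictor at ln S values."""
        x = np.asarray(logS, dtype=float)
        va = self.cov_params[0, 0]
        if self.slope_fixed:
            return np.full_like(x, va)
        vb = self.cov_params[1, 1]
        cab = self.cov_params[0, 1]
        return va + 2.0 * x * cab + x * x * vb

    def predict(self, S, level: float | None = None):
        """Predicted failure fraction mu(S), optionally with a confidence band.

        The band is a normal-approximation interval on the link scale,
        transformed through the inverse link; it is returned as
        ``(mu, (lower, upper))`` with both bounds inside [0, 1].
        """
        S_arr = np.asarray(S, dtype=float)
        if np.any(S_arr <= 0) or not np.all(np.isfinite(S_arr)):
            raise InputError("S must be positive and finite")
        scalar = S_arr.ndim == 0
        logS = np.log(np.atleast_1d(S_arr))
        eta = self.alpha + self.b * logS
        mu = np.exp(-np.exp(eta))
        if level is None:
            return float(mu[0]) if scalar else mu
        if not 0 < level < 1:
            raise InputError(f"level must be in (0, 1), got {level}")
        z = stats.norm.ppf(0.5 + level / 2.0)
        sd = np.sqrt(np.maximum(self.link_variance(logS), 0.0))
        lo = np.exp(-np.exp(eta + z * sd))  # mu decreases in eta
        hi = np.exp(-np.exp(eta - z * sd))
        if scalar:
            return float(mu[0]), (float(lo[0]), float(hi[0]))
        return mu, (lo, hi)

    def activity(self, level: float = 0.95, method: str = "band_inversion"):
        """Clonogenic activity with its confidence interval; see
        :func:`cooplda.activity.clonogenic_activity`."""
        from .activity import clonogenic_activity

        return clonogenic_activity(self, level=level, method=method)

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        g = self.group
        lines = [
            "Limiting dilution power-law model"
            + ("  (slope fixed: b = 1)" if self.slope_fixed else ""),
            "=" * 64,
            f"treatment: {g.treatment}    replicate: {g.replicate}",
            f"dilutions: {len(g)}    wells: {int(g.n_wells.sum())}"
            f"    negative wells: {int(g.n_negative.sum())}",
            f"converged: {self.converged}    iterations: {self.n_iter}",
            "-" * 64,
            f"{'':12s}{'coef':>12s}{'std err':>12s}{'[0.025':>12s}{'0.975]':>12s}",
        ]
        z = stats.norm.ppf(0.975)
        names = ["alpha"] if self.slope_fixed else ["alpha", "b"]
        for i, name in enumerate(names):
            est, se = self.params[i], self.bse[i]
            lines.append(
                f"{name:12s}{est:12.4f}{se:12.4f}{est - z * se:12.4f}{est + z * se:12.4f}"
            )
        p = np.exp(self.alpha)
        a = np.exp(-self.alpha / self.b)
        lines += [
            "-" * 64,
            f"p = exp(alpha) = {p:.6g}    b = {self.b:.4f}",
            f"clonogenic activity a = exp(-alpha/b) = {a:.6g} cells/well",
            f"log-likelihood {self.llf:.4f}    deviance {self.deviance:.4f}"
            f"    AIC {self.aic:.4f}",
        ]
        return "\n".join(lines)


@dataclass(frozen=True)
class ModelComparison:
    """Likelihood-ratio comparison of free-slope vs fixed-slope (b=1) fits."""

    delta_deviance: float
    lrt_p: float
    delta_aic: float
    df: int = 1


def compare_models(fit_free: LDAResults, fit_fixed: LDAResults) -> ModelComparison:
    """Likelihood-ratio test of the power-law model against the single-hit model.

    ``fit_fixed`` (b fixed at 1) must be nested in ``fit_free`` and fitted to
    the identical observations.  The deviance difference is referred to a
    chi-squared distribution with one degree of freedom; ``delta_aic`` is
    ``aic_fixed - aic_free`` (positive favours the power-law model).
    """
    if fit_free.slope_fixed or not fit_fixed.slope_fixed:
        raise InputError("expected (free-slope, fixed-slope) results, in that order")
    mf, mx = fit_free.model, fit_fixed.model
    same = (
        np.array_equal(mf.S, mx.S)
        and np.array_equal(mf.n, mx.n)
        and np.array_equal(mf.y, mx.y)
    )
    if not same:
        raise InputError("model comparison requires identical observation sets")
    delta_dev = max(fit_fixed.deviance - fit_free.deviance, 0.0)
    lrt_p = float(stats.chi2.sf(delta_dev, df=1)) if delta_dev > 0 else 1.0
    return ModelComparison(
        delta_deviance=delta_dev,
        lrt_p=lrt_p,
        delta_aic=fit_fixed.aic - fit_free.aic,
    )


# -- functional wrappers ------------------------------------------------------


def fit_loglog_glm(group: AssayGroup, slope_fixed: bool = False) -> LDAResults:
    """Fit the power-law clonogenic growth model to one assay group."""
    return LimitingDilutionModel(group, slope_fixed=slope_fixed).fit()


def predict_failure_fraction(fit: LDAResults, S, level: float = 0.95):
    """Predicted failure fraction at S with a confidence band (see
    :meth:`LDAResults.predict`)."""
    return fit.predict(S, level=level)


def fit_summary_table(results: list[LDAResults]):
    """One-row-per-fit summary table (CSV-ready)."""
    import pandas as pd

    rows = []
    for r in results:
        se = r.bse
        rows.append(
            {
                "treatment": r.group.treatment,
                "replicate": r.group.replicate,
                "alpha": r.alpha,
                "b": r.b,
                "se_alpha": se[0],
                "se_b": np.nan if r.slope_fixed else se[1],
                "cov_ab": np.nan if r.slope_fixed else r.cov_params[0, 1],
                "deviance": r.deviance,
                "aic": r.aic,
                "converged": r.converged,
                "slope_fixed": r.slope_fixed,
            }
        )
    return pd.DataFrame(rows)
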