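"""Paternal-age-effect regression of de novo SNV counts.

The count of validated de novo SNVs in a child is modelled as Poisson with
mean linear in the father's age at that child's birth (identity link, the
default, so the slope reads directly as additional SNVs per year), or
log-linear (the slope is then reported as the marginal SNVs/year at the mean
age).  Fitted cohort-wide and per family; exposed both as a
statsmodels-style Model/Results pair and as thin functional wrappers used by
the pipeline.
"""

from __future__ import annotations

import warnings
from contextlib import contextmanager
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import DomainWarning


@contextmanager
def _quiet_glm():
    # statsmodels re-arms DomainWarning with simplefilter("always"); the
    # identity link is intentional here, so silence it locally
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DomainWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

        warnings.simplefilter("ignore", PerfectSeparationWarning)
        yield

__all__ = [
    "PaeFit",
    "PaternalAgeModel",
    "PaternalAgeResults",
    "fit_pae",
    "fit_family_slopes",
    "rank_families",
]


@dataclass
class PaeFit:
    """Summary of one Poisson paternal-age fit."""

    scope: str  # "cohort" or a family id
    intercept: float  # expected SNVs at age 0 (identity link)
    slope: float  # SNVs per additional year of paternal age
    slope_ci_low: float
    slope_ci_high: float
    p_value: float
    n_children: int
    link: str

    def __post_init__(self):
        if not (self.slope_ci_low <= self.slope <= self.slope_ci_high):
            raise ValueError("slope must lie inside its confidence interval")

    def to_dict(self) -> dict:
        return asdict(self)


class PaternalAgeModel:
    """Poisson regression of per-child DNM counts on paternal age.

    Parameters
    ----------
    counts : array-like of non-negative integers, one per child.
    ages : paternal age (years) at each child's birth.
    link : "identity" (default; slope = SNVs/year) or "log".

    Examples
    --------
    >>> m = PaternalAgeModel([30, 40], [20.0, 30.0])
    >>> res = m.fit()
    >>> round(res.slope, 6)
    1.0
    """

    def __init__(self, counts, ages, link: str = "identity"):
        counts = np.asarray(counts, dtype=float)
        ages = np.asarray(ages, dtype=float)
        if counts.shape != ages.shape or counts.ndim != 1:
            raise ValueError("counts and ages must be equal-length 1-D arrays")
        if np.any(counts < 0) or np.any(counts != np.round(counts)):
            raise ValueError("counts must be non-negative integers")
        if np.any(ages <= 0):
            raise ValueError("ages must be positive")
        if len(np.unique(ages)) < 2:
            raise ValueError("need at least 2 distinct ages to estimate a slope")
        if link not in ("identity", "log"):
            raise ValueError(f"unknown link {link!r}")
        self.counts = counts
        self.ages = ages
        self.link = link

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        count_col: str = "n_validated",
        age_col: str = "paternal_age",
        link: str = "identity",
    ) -> "PaternalAgeModel":
        return cls(df[count_col].to_numpy(), df[age_col].to_numpy(), link=link)

    def fit(self, scope: str = "cohort", ci_method: str = "wald") -> "PaternalAgeResults":
        y, x = self.counts, self.ages
        X = sm.add_constant(x)
        if self.link == "identity":
            fam = sm.families.Poisson(link=sm.families.links.Identity())
            # OLS start keeps the identity-link mean positive over the data range
            start = np.linalg.lstsq(X, y, rcond=None)[0]
            mu0 = X @ start
            if np.any(mu0 <= 0):
                start = np.array([max(y.mean(), 0.5), 0.0])
            try:
                with _quiet_glm():
                    glm = sm.GLM(y, X, family=fam)
                    res = glm.fit(start_params=start, maxiter=200)
                mu = res.predict(X)
            except (ValueError, np.linalg.LinAlgError):
                res, mu = None, np.array([-1.0])
            if res is None or np.any(mu <= 0) or not np.isfinite(res.llf):
                # boundary case (e.g. a zero count at an extreme age): the
                # unconstrained IRLS solution leaves the feasible region, so
                # maximise the likelihood under mu_i >= eps directly
                res = _fit_identity_constrained(y, x)
                if res is None:
                    bad = x[mu <= 0]
                    raise ValueError(
                        f"identity-link mean non-positive at ages {np.round(bad, 1).tolist()}"
                    )
        else:
            with _quiet_glm():
                res = sm.GLM(y, X, family=sm.families.Poisson()).fit(maxiter=200)
        return PaternalAgeResults(self, res, scope=scope, ci_method=ci_method)


class _ConstrainedPoissonResults:
    """Minimal GLM-results shim for the constrained identity-link fallback."""

    def __init__(self, params, cov, y, x):
        self.params = params
        self._cov = cov
        self._y, self._x = y, x
        mu = params[0] + params[1] * x
        self.mu = np.maximum(mu, 1e-10)
        self.llf = float(np.sum(y * np.log(self.mu) - self.mu))
        sat = np.sum(y[y > 0] * np.log(y[y > 0]) - y[y > 0])
        self.deviance = float(2 * (sat - np.sum(y * np.log(self.mu) - self.mu)))
        self.bse = np.sqrt(np.diag(cov))

    @property
    def pvalues(self):
        from scipy.stats import norm

        z = self.params / np.where(self.bse > 0, self.bse, np.inf)
        return 2 * norm.sf(np.abs(z))

    def conf_int(self):
        z = 1.959963984540054
        return np.column_stack([self.params - z * self.bse, self.params + z * self.bse])

    def predict(self, X):
        X = np.atleast_2d(X)
        return X @ self.params


def _fit_identity_constrained(y, x, eps: float = 1e-8):
    """Maximum-likelihood identity-link Poisson fit with mu_i >= eps."""
    from scipy.optimize import minimize

    X = np.column_stack([np.ones_like(x), x])

    def nll(p):
        mu = X @ p
        if np.any(mu < eps):
            return np.inf
        return float(np.sum(mu - y * np.log(mu)))

    starts = [
        np.linalg.lstsq(X, np.maximum(y, 0.5), rcond=None)[0],
        np.array([max(np.mean(y), 0.5), 0.0]),
    ]
    best = None
    for s0 in starts:
        if np.any(X @ s0 < eps):
            s0 = np.array([max(np.mean(y), 0.5), 0.0])
        r = minimize(
            nll, s0, method="SLSQP",
            constraints=[{"type": "ineq", "fun": lambda p: X @ p - eps}],
            options={"maxiter": 500, "ftol": 1e-10},
        )
        if r.success and (best is None or r.fun < best.fun):
            best = r
    if best is None:
        return None
    p = best.x
    mu = np.maximum(X @ p, eps)
    # observed information for the Poisson identity-link log-likelihood
    w = y / mu**2
    info = X.T @ (w[:, None] * X)
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.full((2, 2), np.nan)
    return _ConstrainedPoissonResults(p, cov, y, x)


class PaternalAgeResults:
    """Results wrapper: estimates, Wald/profile CIs, diagnostics, summary()."""

    def __init__(self, model: PaternalAgeModel, glm_results, scope: str = "cohort", ci_method: str = "wald"):
        self.model = model
        self._res = glm_results
        self.scope = scope
        self.ci_method = ci_method
        self.intercept = float(glm_results.params[0])
        self._raw_slope = float(glm_results.params[1])
        if ci_method == "profile":
            lo, hi = self._profile_ci()
        else:
            lo, hi = (float(v) for v in glm_results.conf_int()[1])
        if model.link == "identity":
            self.slope, self.slope_ci = self._raw_slope, (lo, hi)
        else:
            # marginal effect at the mean age: d mu / d age = b * mu(age_bar)
            mu_bar = float(np.exp(self.intercept + self._raw_slope * model.ages.mean()))
            self.slope = self._raw_slope * mu_bar
            self.slope_ci = (lo * mu_bar, hi * mu_bar)
        self.p_value = float(glm_results.pvalues[1])
        self.n = len(model.counts)

    def _profile_ci(self, alpha: float = 0.05) -> tuple[float, float]:
        """Likelihood-ratio CI for the slope by bisection on the profile deviance."""
        from scipy.optimize import brentq
        from scipy.stats import chi2

        y, x = self.model.counts, self.model.ages
        crit = chi2.ppf(1 - alpha, 1)
        ll_hat = self._res.llf

        def prof_ll(b):
            # refit intercept with slope fixed: offset the linear predictor
            if self.model.link == "identity":
                fam = sm.families.Poisson(link=sm.families.links.Identity())
            else:
                fam = sm.families.Poisson()
            off = b * x
            with _quiet_glm():
                r = sm.GLM(y, np.ones((len(y), 1)), family=fam, offset=off).fit(
                    start_params=[max(np.mean(y - off), 0.5)] if self.model.link == "identity" else None
                )
            return r.llf

        def g(b):
            return 2 * (ll_hat - prof_ll(b)) - crit

        b_hat = self._raw_slope
        se = float(self._res.bse[1])
        lo = brentq(g, b_hat - 10 * se, b_hat - 1e-9 * max(abs(b_hat), 1))
        hi = brentq(g, b_hat + 1e-9 * max(abs(b_hat), 1), b_hat + 10 * se)
        return float(lo), float(hi)

    @property
    def deviance(self) -> float:
        return float(self._res.deviance)

    def predict(self, ages) -> np.ndarray:
        ages = np.atleast_1d(np.asarray(ages, dtype=float))
        X = np.column_stack([np.ones_like(ages), ages])
        return self._res.predict(X)

    def to_fit(self) -> PaeFit:
        return PaeFit(
            scope=self.scope,
            intercept=self.intercept,
            slope=self.slope,
            slope_ci_low=self.slope_ci[0],
            slope_ci_high=self.slope_ci[1],
            p_value=self.p_value,
            n_children=self.n,
            link=self.model.link,
        )

    def summary(self) -> str:
        f = self.to_fit()
        lines = [
            "Paternal-age-effect Poisson regression",
            f"  scope: {f.scope}   link: {f.link}   n children: {f.n_children}",
            f"  intercept (SNVs at age 0): {f.intercept:8.3f}",
            f"  slope (SNVs/year):         {f.slope:8.3f}  "
            f"[95% CI {f.slope_ci_low:.3f}, {f.slope_ci_high:.3f}]  p = {f.p_value:.3g}",
            f"  deviance: {self.deviance:.2f}",
        ]
        return "\n".join(lines)


def fit_pae(counts, ages, link: str = "identity", scope: str = "cohort", ci_method: str = "wald") -> PaeFit:
    """One-call Poisson paternal-age fit returning a :class:`PaeFit`."""
    return PaternalAgeModel(counts, ages, link=link).fit(scope=scope, ci_method=ci_method).to_fit()


def fit_family_slopes(
    per_child: pd.DataFrame,
    link: str = "identity",
    count_col: str = "n_validated",
    age_col: str = "paternal_age",
) -> tuple[pd.DataFrame, list[str]]:
    """Independent per-family fits; families with <2 children are skipped (flagged).

    ``per_child`` needs family_id plus the count and age columns.  Returns
    (fits table, skipped family ids).  Negative slopes are legal outputs.
    """
    rows, skipped = [], []
    for fam, grp in per_child.groupby("family_id"):
        if len(grp) < 2 or grp[age_col].nunique() < 2:
            skipped.append(str(fam))
            continue
        fit = fit_pae(grp[count_col].to_numpy(), grp[age_col].to_numpy(), link=link, scope=str(fam))
        rows.append(fit.to_dict())
    return pd.DataFrame(rows), skipped


def rank_families(fits: pd.DataFrame) -> pd.DataFrame:
    """Ascending stable sort by slope; ties broken by family id."""
    if len(fits) == 0:
        raise ValueError("no fits to rank")
    return fits.sort_values(["slope", "scope"], kind="stable").reset_index(drop=True)
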