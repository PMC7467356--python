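"""Random-intercept mixed model and variance decomposition per glycan trait.

The model is

    y_ij = b0 + b_age age_ij + b_sex sex_ij + u_j + e_ij,
    u_j ~ N(0, s2_country),  e_ij ~ N(0, s2_resid),

with j indexing country of residence.  REML estimates are obtained by a
one-dimensional profile over the variance ratio lambda = s2_country /
s2_resid: for fixed lambda the GLS solution for the coefficients and the
residual variance is closed form (the marginal covariance is block
compound-symmetric, so all quantities reduce to per-country sufficient
statistics), and lambda >= 0 is optimized by bounded scalar minimization
with the boundary lambda = 0 admissible.

Variance explained follows the marginal/conditional R2 framework for
mixed models: each component (country random intercept, each centered
fixed-effect term, residual) is reported as a percentage of
var(fixed predictor) + s2_country + s2_resid.  The significance of the
country random effect is assessed by a likelihood ratio test of the ML
fits with and without the random intercept, referred to chi-square with
1 df by default (the 50:50 chi0:chi1 boundary mixture is available).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "TraitVarianceModel",
    "TraitVarianceResults",
    "fit_lmm_reml",
    "variance_explained",
    "lrt_random_effect",
    "decompose_variance",
    "ConvergenceError",
]

_LOG_2PI = math.log(2.0 * math.pi)


class ConvergenceError(RuntimeError):
    """REML profile optimization failed; carries the profile trace."""

    def __init__(self, message: str, trace: pd.DataFrame | None = None):
        super().__init__(message)
        self.trace = trace


class TraitVarianceModel:
    """Random-intercept linear mixed model for one glycan trait.

    Parameters
    ----------
    y : array-like
        Trait values (typically log-scale, batch-corrected).
    age, sex, country : array-like
        Fixed covariates (age in years; sex with exactly two levels) and
        the random-intercept grouping factor.  ``age`` and ``sex`` may be
        None to fit an intercept-only fixed part.
    """

    def __init__(self, y, age=None, sex=None, country=None, trait: str = "trait"):
        if country is None:
            raise ValueError("country grouping factor is required")
        self.trait = trait
        y = np.asarray(y, dtype=float)
        n = len(y)
        if not np.isfinite(y).all():
            raise ValueError("non-finite trait values")
        cols = [np.ones(n)]
        names = ["intercept"]
        if age is not None:
            cols.append(np.asarray(age, dtype=float))
            names.append("age")
        self._sex_levels: Tuple = ()
        if sex is not None:
            sex = np.asarray(sex)
            levels = sorted(pd.unique(sex).tolist())
            if len(levels) != 2:
                raise ValueError(
                    f"sex must have exactly two levels, got {levels}")
            self._sex_levels = tuple(levels)
            cols.append((sex == levels[1]).astype(float))
            names.append(f"sex[{levels[1]}]")
        X = np.column_stack(cols)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("collinear fixed-effect design")
        groups = pd.Categorical(np.asarray(country))
        if len(groups.categories) < 2:
            raise ValueError("need at least 2 countries")
        if n <= X.shape[1] + 2:
            raise ValueError("too few observations for the fixed design")
        self.y = y
        self.X = X
        self.exog_names: List[str] = names
        self.groups = groups
        self.nobs = n
        self.k_fe = X.shape[1]
        # per-group sufficient statistics
        self._group_idx = [np.flatnonzero(groups.codes == k)
                           for k in range(len(groups.categories))]
        self._nj = np.array([len(ix) for ix in self._group_idx])
        self._Sx = np.vstack([X[ix].sum(axis=0) for ix in self._group_idx])
        self._Sy = np.array([y[ix].sum() for ix in self._group_idx])
        self._XtX = X.T @ X
        self._Xty = X.T @ y
        self._yty = float(y @ y)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, trait: str,
                       age: str | None = "age", sex: str | None = "sex",
                       country: str = "country") -> "TraitVarianceModel":
        return cls(
            data[trait],
            data[age] if age is not None else None,
            data[sex] if sex is not None else None,
            data[country], trait=trait)

    # -- profile machinery ---------------------------------------------------

    def _gls(self, lam: float):
        """GLS at fixed lambda via per-group downdates of the cross-products."""
        c = lam / (1.0 + self._nj * lam)          # per group
        XtWX = self._XtX - (self._Sx * c[:, None]).T @ self._Sx
        XtWy = self._Xty - self._Sx.T @ (c * self._Sy)
        ytWy = self._yty - float(c @ self._Sy**2)
        beta = np.linalg.solve(XtWX, XtWy)
        rss = ytWy - float(beta @ XtWy)
        return beta, rss, XtWX

    def _reml_neg2(self, lam: float) -> float:
        n, p = self.nobs, self.k_fe
        beta, rss, XtWX = self._gls(lam)
        sigma2 = rss / (n - p)
        logdet_v = float(np.log1p(self._nj * lam).sum())
        sign, logdet_x = np.linalg.slogdet(XtWX)
        return ((n - p) * (1.0 + math.log(2.0 * math.pi * sigma2))
                + logdet_v + logdet_x)

    def _ml_neg2(self, lam: float) -> float:
        n = self.nobs
        beta, rss, _ = self._gls(lam)
        sigma2 = rss / n
        logdet_v = float(np.log1p(self._nj * lam).sum())
        return n * (1.0 + math.log(2.0 * math.pi * sigma2)) + logdet_v

    def _profile(self, objective, lam_max: float = 1e4):
        grid = np.concatenate([[0.0], np.logspace(-6, math.log10(lam_max), 81)])
        values = np.array([objective(l) for l in grid])
        k = int(np.argmin(values))
        trace = pd.DataFrame({"lambda": grid, "neg2loglik": values})
        lo = grid[max(k - 1, 0)]
        hi = grid[min(k + 1, len(grid) - 1)]
        if k == 0:
            # check boundary: is 0 better than the best interior refinement?
            res = optimize.minimize_scalar(objective, bounds=(0.0, hi),
                                           method="bounded",
                                           options={"xatol": 1e-10})
            lam = float(res.x) if res.fun < values[0] else 0.0
        else:
            res = optimize.minimize_scalar(objective, bounds=(lo, hi),
                                           method="bounded",
                                           options={"xatol": 1e-10})
            if not res.success:
                raise ConvergenceError("profile optimization failed", trace)
            lam = float(res.x)
        if lam > 0:
            # polish in a narrow window around the first solution
            res = optimize.minimize_scalar(
                objective, bounds=(0.995 * lam, 1.005 * lam + 1e-12),
                method="bounded", options={"xatol": 1e-12})
            if res.fun <= objective(lam):
                lam = float(res.x)
        if objective(0.0) <= objective(lam):
            lam = 0.0
        return lam, trace

    # -- fitting ---------------------------------------------------------------

    def fit(self, method: str = "reml") -> "TraitVarianceResults":
        if method not in ("reml", "ml"):
            raise ValueError("method must be 'reml' or 'ml'")
        objective = self._reml_neg2 if method == "reml" else self._ml_neg2
        lam, trace = self._profile(objective)
        beta, rss, XtWX = self._gls(lam)
        dof = self.nobs - self.k_fe if method == "reml" else self.nobs
        sigma2_e = rss / dof
        sigma2_u = lam * sigma2_e
        # standard errors of the fixed effects at the estimated lambda
        cov_beta = sigma2_e * np.linalg.inv(XtWX)
        return TraitVarianceResults(
            model=self, method=method, lam=lam,
            fe_params=pd.Series(beta, index=self.exog_names),
            bse=pd.Series(np.sqrt(np.diag(cov_beta)), index=self.exog_names),
            sigma2_country=float(sigma2_u), sigma2_resid=float(sigma2_e),
            neg2loglik=float(objective(lam)), profile_trace=trace,
            converged=True)

    def loglike_ml(self, lam: float) -> float:
        return -0.5 * self._ml_neg2(lam)


@dataclass
class TraitVarianceResults:
    """REML/ML estimates and the variance decomposition of one trait."""

    model: TraitVarianceModel
    method: str
    lam: float
    fe_params: pd.Series
    bse: pd.Series
    sigma2_country: float
    sigma2_resid: float
    neg2loglik: float
    profile_trace: pd.DataFrame
    converged: bool

    @property
    def loglike(self) -> float:
        return -0.5 * self.neg2loglik

    @property
    def icc(self) -> float:
        denom = self.sigma2_country + self.sigma2_resid
        return self.sigma2_country / denom if denom > 0 else 0.0

    def fixed_predictor(self) -> np.ndarray:
        return self.model.X @ self.fe_params.to_numpy()

    def variance_explained(self) -> Dict[str, float]:
        """Percent of total variance per component.

        Total variance = var(fixed predictor) + s2_country + s2_resid.
        Per-variable fixed shares use the variance of each centered
        component; their covariance remainder is reported separately.
        """
        X = self.model.X
        beta = self.fe_params.to_numpy()
        fixed = X @ beta
        var_fixed = float(np.var(fixed))
        total = var_fixed + self.sigma2_country + self.sigma2_resid
        if total <= 0:
            raise ValueError("zero total variance; decomposition undefined")
        out: Dict[str, float] = {}
        explained_parts = 0.0
        for j, name in enumerate(self.model.exog_names):
            if name == "intercept":
                continue
            comp = beta[j] * X[:, j]
            share = 100.0 * float(np.var(comp)) / total
            key = "sex" if name.startswith("sex[") else name
            out[key] = share
            explained_parts += share
        out["country"] = 100.0 * self.sigma2_country / total
        out["fixed_total"] = 100.0 * var_fixed / total
        out["fixed_covariance"] = out["fixed_total"] - explained_parts
        out["residual"] = 100.0 * self.sigma2_resid / total
        return out

    def lrt_random_effect(self, boundary_mixture: bool = False) -> Dict[str, float]:
        """LRT of the country random intercept against the fixed-only model."""
        model = self.model
        full = model.fit(method="ml") if self.method != "ml" else self
        ll_full = full.loglike
        ll_reduced = model.loglike_ml(0.0)
        lrt = 2.0 * (ll_full - ll_reduced)
        if lrt < -1e-6:
            raise ConvergenceError(
                f"negative LRT statistic ({lrt:.3g}); refit required",
                self.profile_trace)
        lrt = max(lrt, 0.0)
        p = float(stats.chi2.sf(lrt, 1))
        if boundary_mixture:
            p = 0.5 * p if lrt > 0 else 1.0
        return {"statistic": lrt, "pvalue": p}

    def summary(self) -> str:
        ve = self.variance_explained()
        lrt = self.lrt_random_effect()
        lines = [
            f"Random-intercept mixed model ({self.method.upper()}): "
            f"{self.model.trait}",
            "=" * 64,
            f"{'n obs':<28}{self.model.nobs:>12}",
            f"{'n countries':<28}{len(self.model.groups.categories):>12}",
            "",
            f"{'':<14}{'coef':>12}{'std err':>12}",
        ]
        for name in self.fe_params.index:
            lines.append(f"{name:<14}{self.fe_params[name]:>12.5f}"
                         f"{self.bse[name]:>12.5f}")
        lines += [
            "",
            f"{'sigma2 country':<28}{self.sigma2_country:>12.5f}",
            f"{'sigma2 residual':<28}{self.sigma2_resid:>12.5f}",
            f"{'ICC (country)':<28}{self.icc:>12.4f}",
            "",
            "Variance explained (% of total):",
        ]
        for key in ("country", "age", "sex", "residual"):
            if key in ve:
                lines.append(f"  {key:<26}{ve[key]:>12.2f}")
        lines.append(f"{'LRT country p-value':<28}{lrt['pvalue']:>12.3e}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Functional wrappers


def fit_lmm_reml(y, age=None, sex=None, country=None,
                 trait: str = "trait") -> TraitVarianceResults:
    """REML fit of the random-intercept model (functional form)."""
    return TraitVarianceModel(y, age, sex, country, trait=trait).fit()


def variance_explained(fit: TraitVarianceResults) -> Dict[str, float]:
    return fit.variance_explained()


def lrt_random_effect(fit: TraitVarianceResults,
                      boundary_mixture: bool = False) -> Dict[str, float]:
    return fit.lrt_random_effect(boundary_mixture=boundary_mixture)


def decompose_variance(traits: pd.DataFrame, metadata: pd.DataFrame,
                       age: str = "age", sex: str = "sex",
                       country: str = "country") -> pd.DataFrame:
    """Variance decomposition table for every trait column.

    ``traits`` may carry plain trait columns or a (subclass, trait)
    MultiIndex; the result has one row per trait with the percentages of
    variability explained by country, age and sex and the LRT p-value of
    the country random effect.
    """
    meta = metadata.reindex(traits.index)
    rows = []
    columns = traits.columns
    for col in columns:
        if isinstance(col, tuple):
            subclass, trait = col
        else:
            subclass, trait = "", col
        res = TraitVarianceModel(
            traits[col], meta[age], meta[sex], meta[country],
            trait=str(trait)).fit()
        ve = res.variance_explained()
        lrt = res.lrt_random_effect()
        rows.append({
            "subclass": subclass, "trait": trait,
            "country_pct": ve["country"], "age_pct": ve.get("age", 0.0),
            "sex_pct": ve.get("sex", 0.0),
            "residual_pct": ve["residual"],
            "lrt_pvalue": lrt["pvalue"],
        })
    return pd.DataFrame(rows)
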