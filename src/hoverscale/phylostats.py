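"""Log-log scaling regressions (OLS and PGLS under Brownian motion),
Blomberg's K phylogenetic signal, allometry classification, and covariate
adjustment.

Allometric scaling is estimated as the slope of ``log10 y`` on ``log10 x``
across species means.  PGLS generalises OLS by giving the residuals the
Brownian-motion covariance implied by the phylogeny (``C[i, j]`` = shared
branch length of species *i* and *j*), so shared ancestry does not masquerade
as an adaptive trend; on a star phylogeny it reduces exactly to OLS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

from .errors import (
    CollinearityWarning,
    DegenerateTraitError,
    InvalidParameterError,
    LabelMismatchError,
)
from .trees import cholesky_or_raise, vcv_matrix

__all__ = [
    "ScalingFit",
    "SignalResult",
    "ScalingRegression",
    "ols_loglog",
    "pgls_loglog",
    "blomberg_k",
    "allometry_classify",
    "covariate_adjustment",
    "CovariateAdjustedFit",
]


@dataclass
class ScalingFit:
    """A fitted log10-log10 scaling relation (one row of a results table)."""

    metric: str
    n: int
    slope: float
    intercept: float
    ci_low: float
    ci_high: float
    r2: float
    p: float
    method: str   # "OLS" or "PGLS-BM"

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.ci_low, self.ci_high)

    def as_dict(self) -> dict:
        return {
            "metric": self.metric, "n": self.n, "slope": self.slope,
            "intercept": self.intercept, "ci_low": self.ci_low,
            "ci_high": self.ci_high, "r2": self.r2, "p": self.p,
            "method": self.method,
        }


@dataclass
class SignalResult:
    """Blomberg's K with its permutation p-value."""

    trait: str
    K: float
    p: float
    n_permutations: int


class ScalingRegression(BaseEstimator):
    """Sklearn-style estimator for log-log scaling fits.

    Parameters
    ----------
    method : {"ols", "pgls"}
        Ordinary least squares, or generalised least squares with the
        Brownian-motion covariance from ``tree``.
    tree : dendropy.Tree, optional
        Required for ``method="pgls"``; tip labels must cover the species
        index of the data passed to :meth:`fit`.
    conf_level : float
        Confidence level of the slope interval (t-distribution, n-2 df).

    Fitted attributes: ``slope_``, ``intercept_``, ``ci95_``, ``r_squared_``,
    ``pvalue_``, ``n_``.
    """

    def __init__(self, method: str = "ols", tree: dendropy.Tree = None,
                 conf_level: float = 0.95):
        self.method = method
        self.tree = tree
        self.conf_level = conf_level

    def fit(self, x, y):
        if self.method not in ("ols", "pgls"):
            raise InvalidParameterError("method must be 'ols' or 'pgls'")
        x = pd.Series(x) if not isinstance(x, pd.Series) else x
        y = pd.Series(y) if not isinstance(y, pd.Series) else y
        if len(x) != len(y):
            raise InvalidParameterError("x and y must have equal length")
        n = len(x)
        if n < 3:
            raise InvalidParameterError("need n >= 3")
        xv = x.to_numpy(dtype=float)
        yv = y.to_numpy(dtype=float)
        if np.any(xv <= 0) or np.any(yv <= 0):
            raise InvalidParameterError("log-log fit requires strictly positive data")
        lx = np.log10(xv)
        ly = np.log10(yv)
        if np.ptp(lx) == 0:
            raise DegenerateTraitError("predictor has zero variance")

        if self.method == "pgls":
            if self.tree is None:
                raise InvalidParameterError("PGLS requires a tree")
            C = vcv_matrix(self.tree)
            labels = list(x.index)
            missing = set(map(str, labels)) - set(C.index)
            if missing:
                raise LabelMismatchError(f"species not in tree: {sorted(missing)}")
            Cm = C.loc[labels, labels].to_numpy()
            L = cholesky_or_raise(Cm)
        else:
            L = None

        X = np.column_stack([np.ones(n), lx])
        self._finalize(X, ly, L, n, str(getattr(y, "name", "") or ""))
        return self

    def _finalize(self, X, ly, L, n, metric):
        from scipy.linalg import solve_triangular

        if L is None:
            Xw, yw = X, ly
            method_name = "OLS"
        else:
            Xw = solve_triangular(L, X, lower=True)
            yw = solve_triangular(L, ly, lower=True)
            method_name = "PGLS-BM"
        XtX = Xw.T @ Xw
        beta = np.linalg.solve(XtX, Xw.T @ yw)
        resid = yw - Xw @ beta
        df = n - 2
        rss = float(resid @ resid)
        s2 = rss / df
        cov = s2 * np.linalg.inv(XtX)
        se_slope = float(np.sqrt(cov[1, 1]))
        tcrit = stats.t.ppf(0.5 + self.conf_level / 2.0, df)
        slope = float(beta[1])
        # R^2 against the (G)LS intercept-only model
        ones_w = Xw[:, 0]
        mu = float((ones_w @ yw) / (ones_w @ ones_w))
        tss = float(np.sum((yw - mu * ones_w) ** 2))
        r2 = 0.0 if tss == 0 else max(0.0, 1.0 - rss / tss)
        if se_slope == 0:
            pval = 0.0 if slope != 0 else 1.0
        else:
            pval = float(2.0 * stats.t.sf(abs(slope) / se_slope, df))
        self.slope_ = slope
        self.intercept_ = float(beta[0])
        self.se_slope_ = se_slope
        self.ci95_ = (slope - tcrit * se_slope, slope + tcrit * se_slope)
        self.r_squared_ = r2
        self.pvalue_ = pval
        self.n_ = n
        self.method_ = method_name
        self.metric_ = metric

    def result(self, metric: str = "") -> ScalingFit:
        return ScalingFit(
            metric=metric or self.metric_, n=self.n_, slope=self.slope_,
            intercept=self.intercept_, ci_low=self.ci95_[0],
            ci_high=self.ci95_[1], r2=self.r_squared_, p=self.pvalue_,
            method=self.method_,
        )


def ols_loglog(x, y, metric: str = "") -> ScalingFit:
    """OLS regression of log10(y) on log10(x); CI from t with n-2 df."""
    return ScalingRegression(method="ols").fit(x, y).result(metric)


def pgls_loglog(tree: dendropy.Tree, x: pd.Series, y: pd.Series,
                metric: str = "") -> ScalingFit:
    """PGLS (Brownian motion) regression of log10(y) on log10(x).

    ``x`` and ``y`` must be species-indexed Series matching the tree tips.
    """
    if not isinstance(x, pd.Series) or not isinstance(y, pd.Series):
        raise InvalidParameterError("PGLS needs species-indexed Series")
    if list(x.index) != list(y.index):
        raise LabelMismatchError("x and y species indices differ")
    return ScalingRegression(method="pgls", tree=tree).fit(x, y).result(metric)


def blomberg_k(
    tree: dendropy.Tree,
    trait: pd.Series,
    n_perm: int = 999,
    seed: int | None = None,
) -> SignalResult:
    """Blomberg's K and its tip-shuffling permutation test.

    ``K`` is the ratio of the observed mean-squared trait deviation from the
    phylogenetic mean (MSE0) over the phylogenetically corrected one (MSE),
    standardised by the expectation of that ratio under Brownian motion on
    this tree, so K = 1 is the Brownian expectation, K > 1 means more signal.
    The p-value is the plus-one-corrected fraction of tip permutations with
    K at least as large as observed.
    """
    if not isinstance(trait, pd.Series):
        raise InvalidParameterError("trait must be a species-indexed Series")
    n = len(trait)
    if n < 4:
        raise InvalidParameterError("need >= 4 species")
    x = trait.to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise DegenerateTraitError("trait has zero variance")
    C = vcv_matrix(tree)
    missing = set(map(str, trait.index)) - set(C.index)
    if missing:
        raise LabelMismatchError(f"species not in tree: {sorted(missing)}")
    Cm = C.loc[list(trait.index), list(trait.index)].to_numpy()
    cholesky_or_raise(Cm)
    Ci = np.linalg.inv(Cm)
    ones = np.ones(n)
    denom_w = ones @ Ci @ ones
    w = (Ci @ ones) / denom_w
    expected = (np.trace(Cm) - n / denom_w) / (n - 1)

    def k_stat(cols: np.ndarray) -> np.ndarray:
        # cols: (n, B) matrix of trait vectors
        a = w @ cols                       # (B,) phylogenetic means
        dev = cols - a
        mse0 = np.sum(dev**2, axis=0)
        mse = np.sum(dev * (Ci @ dev), axis=0)
        return (mse0 / mse) / expected

    K_obs = float(k_stat(x[:, None])[0])
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(x) for _ in range(n_perm)], axis=1)
    K_perm = k_stat(perms)
    p = (1.0 + np.sum(K_perm >= K_obs)) / (n_perm + 1.0)
    return SignalResult(
        trait=str(trait.name or ""), K=K_obs, p=float(p), n_permutations=n_perm
    )


def allometry_classify(fit: ScalingFit, a_sim: float) -> str:
    """Classify a fitted slope against the similarity exponent via its 95% CI.

    ``"negative"`` if the whole CI lies below ``a_sim``, ``"positive"`` if
    above, else ``"isometry"`` (bounds inclusive: a CI touching ``a_sim``
    counts as isometry).
    """
    if fit.ci_high < a_sim:
        return "negative"
    if fit.ci_low > a_sim:
        return "positive"
    return "isometry"


@dataclass
class CovariateAdjustedFit:
    """Mass effect on a kinematic trait after controlling for flight covariates."""

    response: str
    mass_coef: float
    mass_p: float
    mass_partial_r2: float
    covariate_coefs: dict[str, float]
    n: int
    r2_full: float


def covariate_adjustment(
    response: pd.Series,
    covariates: pd.DataFrame,
    mass: pd.Series,
    log_mass: bool = True,
) -> CovariateAdjustedFit:
    """Multiple regression of a kinematic trait on flight covariates plus mass.

    Reports the mass coefficient with its p-value and partial R² after
    covariate control (e.g. flight speed and climb angle).  Near-collinear
    predictors trigger a :class:`CollinearityWarning`.
    """
    n = len(response)
    k = covariates.shape[1] + 1
    if n <= k + 1:
        raise InvalidParameterError("need n > number of predictors + 1")
    mass_term = np.log10(mass.to_numpy(dtype=float)) if log_mass else mass.to_numpy(float)
    X = pd.DataFrame(covariates).copy()
    X["mass"] = mass_term
    Xs = X.to_numpy(dtype=float)
    sd = Xs.std(axis=0)
    if np.any(sd == 0):
        raise DegenerateTraitError("a predictor has zero variance")
    corr = np.corrcoef((Xs - Xs.mean(axis=0)) / sd, rowvar=False)
    off = corr[~np.eye(corr.shape[0], dtype=bool)]
    if np.any(np.abs(off) > 0.999):
        warnings.warn(
            "predictors are nearly collinear; coefficients are unstable",
            CollinearityWarning,
        )
    model = sm.OLS(response.to_numpy(dtype=float), sm.add_constant(Xs)).fit()
    mass_idx = Xs.shape[1]   # last column after the constant
    tval = model.tvalues[mass_idx]
    partial_r2 = float(tval**2 / (tval**2 + model.df_resid))
    return CovariateAdjustedFit(
        response=str(response.name or ""),
        mass_coef=float(model.params[mass_idx]),
        mass_p=float(model.pvalues[mass_idx]),
        mass_partial_r2=partial_r2,
        covariate_coefs={
            c: float(b) for c, b in zip(X.columns[:-1], model.params[1:-1])
        },
        n=n,
        r2_full=float(model.rsquared),
    )
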