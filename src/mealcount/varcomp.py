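"""REML estimation for the random-intercept linear mixed model.

All of the evaluation analyses in this package share one model family::

    y = X beta + Z b + e,   b ~ N(0, sigma2_g I),   e ~ N(0, sigma2_e I)

with a single random intercept per group (tray or rater).  This module fits
that family by restricted maximum likelihood, profiling the criterion down
to one dimension (the variance ratio ``lambda = sigma2_g / sigma2_e``),
which makes the fit deterministic to optimiser tolerance and lets the
balanced one-way case agree with the classical ANOVA method-of-moments
estimator to many decimals.

Inference on fixed-effect contrasts uses t statistics with Satterthwaite
degrees of freedom: for a contrast ``c``, ``f(theta) = Var(c' beta_hat)`` as
a function of the variance components ``theta = (sigma2_g, sigma2_e)``, and

    df = 2 f(theta_hat)^2 / (g' A g)

where ``g`` is the gradient of ``f`` and ``A`` the asymptotic covariance of
``theta_hat`` (inverse REML information), both evaluated numerically.  When
the group variance is estimated on the boundary (zero) the model collapses
to ordinary least squares and ``df = n - p`` exactly.

Negative variance-component estimates are truncated at zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = ["RandomInterceptModel", "RandomInterceptResults"]

_BOUNDARY_LOGLAM = -30.0  # lambda = e^-30: numerically indistinguishable from OLS


class RandomInterceptModel:
    """Linear mixed model with one random intercept per group.

    Parameters
    ----------
    endog : (n,) array
        Response vector.
    exog : (n, p) array
        Fixed-effects design matrix, including any intercept column.
    groups : (n,) array
        Group labels for the random intercept.
    exog_names : sequence of str, optional
        Column names for reporting.
    """

    def __init__(self, endog, exog, groups, exog_names=None):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.atleast_2d(np.asarray(exog, dtype=float))
        if self.exog.shape[0] != self.endog.shape[0]:
            raise ValueError("endog and exog must have the same number of rows")
        self.groups = np.asarray(groups)
        if self.groups.shape[0] != self.endog.shape[0]:
            raise ValueError("groups must align with endog")
        self.nobs, self.k_fe = self.exog.shape
        if self.nobs <= self.k_fe:
            raise ValueError("more fixed-effect parameters than observations")
        self.exog_names = (
            list(exog_names) if exog_names is not None else [f"x{j}" for j in range(self.k_fe)]
        )
        # pre-split rows by group once; order of groups is first-appearance
        _, idx = np.unique(self.groups, return_index=True)
        labels = self.groups[np.sort(idx)]
        self.group_labels = list(labels)
        self._gidx = [np.flatnonzero(self.groups == g) for g in labels]
        self._Xg = [self.exog[i] for i in self._gidx]
        self._yg = [self.endog[i] for i in self._gidx]
        self._ng = np.array([len(i) for i in self._gidx])

    # -- profiled REML pieces ------------------------------------------------

    def _gls_pieces(self, lam: float):
        """X'W^-1 X, X'W^-1 y, y'W^-1 y and log|W| for W = I + lam * J (per group)."""
        p = self.k_fe
        XtWX = np.zeros((p, p))
        XtWy = np.zeros(p)
        ytWy = 0.0
        logdetW = 0.0
        for Xg, yg, ng in zip(self._Xg, self._yg, self._ng):
            c = lam / (1.0 + ng * lam)
            sx = Xg.sum(axis=0)
            sy = yg.sum()
            XtWX += Xg.T @ Xg - c * np.outer(sx, sx)
            XtWy += Xg.T @ yg - c * sx * sy
            ytWy += yg @ yg - c * sy * sy
            logdetW += np.log1p(ng * lam)
        return XtWX, XtWy, ytWy, logdetW

    def _profiled_neg2_reml(self, loglam: float) -> float:
        lam = np.exp(loglam)
        XtWX, XtWy, ytWy, logdetW = self._gls_pieces(lam)
        try:
            beta = np.linalg.solve(XtWX, XtWy)
        except np.linalg.LinAlgError:
            raise ValueError(
                "singular fixed-effects design: some terms are collinear"
            ) from None
        rss = max(ytWy - beta @ XtWy, 0.0)
        dfr = self.nobs - self.k_fe
        sign, logdetA = np.linalg.slogdet(XtWX)
        if sign <= 0:
            return np.inf
        if rss <= 0:  # perfect fit: criterion unbounded below, treat as flat minimum
            return -1.0e300
        return dfr * np.log(rss / dfr) + logdetW + logdetA

    def _profiled_neg2_ml(self, loglam: float) -> float:
        lam = np.exp(loglam)
        XtWX, XtWy, ytWy, logdetW = self._gls_pieces(lam)
        beta = np.linalg.solve(XtWX, XtWy)
        rss = max(ytWy - beta @ XtWy, 0.0)
        if rss <= 0:
            return -1.0e300
        return self.nobs * np.log(rss / self.nobs) + logdetW

    def _neg2_reml_full(self, sigma2_g: float, sigma2_e: float) -> float:
        """Restricted -2 log-likelihood at arbitrary (sigma2_g, sigma2_e)."""
        if sigma2_e <= 0 or sigma2_g < 0:
            return np.inf
        lam = sigma2_g / sigma2_e
        XtWX, XtWy, ytWy, logdetW = self._gls_pieces(lam)
        beta = np.linalg.solve(XtWX, XtWy)
        rss = ytWy - beta @ XtWy
        n, p = self.nobs, self.k_fe
        sign, logdetA = np.linalg.slogdet(XtWX)
        return (
            (n - p) * np.log(sigma2_e)
            + logdetW
            + logdetA
            + rss / sigma2_e
        )

    def fit(self) -> "RandomInterceptResults":
        """Estimate variance components by REML and fixed effects by GLS."""
        res = optimize.minimize_scalar(
            self._profiled_neg2_reml,
            bounds=(_BOUNDARY_LOGLAM, 15.0),
            method="bounded",
            options={"xatol": 1e-12},
        )
        loglam = float(res.x)
        # compare against the OLS boundary (lambda -> 0); truncate there if better
        if self._profiled_neg2_reml(_BOUNDARY_LOGLAM) <= res.fun + 1e-10:
            loglam = _BOUNDARY_LOGLAM
        on_boundary = loglam <= _BOUNDARY_LOGLAM + 1e-6
        lam = 0.0 if on_boundary else float(np.exp(loglam))

        XtWX, XtWy, ytWy, _ = self._gls_pieces(lam)
        beta = np.linalg.solve(XtWX, XtWy)
        rss = ytWy - beta @ XtWy
        sigma2_e = rss / (self.nobs - self.k_fe)
        sigma2_g = lam * sigma2_e
        cov_beta = sigma2_e * np.linalg.inv(XtWX)
        return RandomInterceptResults(
            model=self,
            params=beta,
            cov_params_mat=cov_beta,
            sigma2_group=float(sigma2_g),
            sigma2_resid=float(sigma2_e),
            on_boundary=on_boundary,
        )

    def fit_ml(self) -> "MLFit":
        """Maximum-likelihood fit; used only for likelihood-ratio tests."""
        res = optimize.minimize_scalar(
            self._profiled_neg2_ml,
            bounds=(_BOUNDARY_LOGLAM, 15.0),
            method="bounded",
            options={"xatol": 1e-12},
        )
        loglam = float(res.x)
        if self._profiled_neg2_ml(_BOUNDARY_LOGLAM) <= res.fun + 1e-10:
            loglam = _BOUNDARY_LOGLAM
        lam = 0.0 if loglam <= _BOUNDARY_LOGLAM + 1e-6 else float(np.exp(loglam))
        XtWX, XtWy, ytWy, logdetW = self._gls_pieces(lam)
        beta = np.linalg.solve(XtWX, XtWy)
        rss = max(ytWy - beta @ XtWy, 0.0)
        sigma2_e = rss / self.nobs
        with np.errstate(divide="ignore"):
            neg2 = (
                self.nobs * (np.log(2 * np.pi * sigma2_e) + 1.0) + logdetW
                if sigma2_e > 0
                else -np.inf
            )
        return MLFit(
            params=beta,
            sigma2_group=lam * sigma2_e,
            sigma2_resid=sigma2_e,
            neg2_loglik=float(neg2),
        )


@dataclass
class MLFit:
    params: np.ndarray
    sigma2_group: float
    sigma2_resid: float
    neg2_loglik: float


@dataclass
class RandomInterceptResults:
    """Fitted random-intercept model: GLS fixed effects + REML components."""

    model: RandomInterceptModel
    params: np.ndarray
    cov_params_mat: np.ndarray
    sigma2_group: float
    sigma2_resid: float
    on_boundary: bool

    @property
    def exog_names(self):
        return self.model.exog_names

    @property
    def df_resid(self) -> int:
        return self.model.nobs - self.model.k_fe

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params_mat))

    def cov_params(self) -> np.ndarray:
        return self.cov_params_mat

    # -- Satterthwaite machinery --------------------------------------------

    def _contrast_var(self, sigma2_g: float, sigma2_e: float, c: np.ndarray) -> float:
        lam = sigma2_g / sigma2_e
        XtWX, _, _, _ = self.model._gls_pieces(lam)
        return sigma2_e * float(c @ np.linalg.solve(XtWX, c))

    def _varcomp_cov(self) -> np.ndarray:
        """Asymptotic covariance of (sigma2_g, sigma2_e): inverse REML information."""
        th = np.array([self.sigma2_group, self.sigma2_resid])
        h = 1e-4 * np.maximum(th, 1e-8 * th[1])
        H = np.zeros((2, 2))

        def f(t):
            return self.model._neg2_reml_full(max(t[0], 0.0), t[1])

        for i in range(2):
            for j in range(i, 2):
                ei = np.eye(2)[i] * h[i]
                ej = np.eye(2)[j] * h[j]
                H[i, j] = H[j, i] = (
                    f(th + ei + ej) - f(th + ei - ej) - f(th - ei + ej) + f(th - ei - ej)
                ) / (4 * h[i] * h[j])
        # Var(theta) = 2 * inverse Hessian of -2*loglik
        return 2.0 * np.linalg.inv(H)

    def satterthwaite_df(self, c: np.ndarray) -> float:
        """Satterthwaite denominator df for the contrast ``c' beta``."""
        c = np.asarray(c, dtype=float)
        if self.on_boundary:
            return float(self.df_resid)
        th = np.array([self.sigma2_group, self.sigma2_resid])
        fval = self._contrast_var(*th, c)
        h = 1e-5 * th
        g = np.zeros(2)
        for i in range(2):
            e = np.eye(2)[i] * h[i]
            g[i] = (self._contrast_var(*(th + e), c) - self._contrast_var(*(th - e), c)) / (
                2 * h[i]
            )
        try:
            A = self._varcomp_cov()
            denom = float(g @ A @ g)
        except np.linalg.LinAlgError:
            return float(self.df_resid)
        if denom <= 0 or not np.isfinite(denom):
            return float(self.df_resid)
        df = 2.0 * fval * fval / denom
        # a contrast can never earn more information than the residual df
        return float(np.clip(df, 1.0, self.df_resid))

    # -- inference -----------------------------------------------------------

    def contrast(self, c, value: float = 0.0, alpha: float = 0.05) -> dict:
        """t test and CI for ``c' beta`` against ``value`` (Satterthwaite df)."""
        c = np.asarray(c, dtype=float)
        est = float(c @ self.params)
        se = float(math.sqrt(max(c @ self.cov_params_mat @ c, 0.0)))
        df = self.satterthwaite_df(c)
        if se > 0:
            tstat = (est - value) / se
            p = 2 * stats.t.sf(abs(tstat), df)
        else:
            # degenerate fit with zero residual variance
            at_null = bool(np.isclose(est, value, rtol=1e-8, atol=1e-10))
            tstat = 0.0 if at_null else math.inf
            p = 1.0 if at_null else 0.0
        tcrit = stats.t.ppf(1 - alpha / 2, df)
        return {
            "estimate": est,
            "se": se,
            "df": df,
            "t": float(tstat),
            "p": float(p),
            "ci": (est - tcrit * se, est + tcrit * se),
        }

    def t_test_param(self, name: str, value: float = 0.0, alpha: float = 0.05) -> dict:
        c = np.zeros(self.model.k_fe)
        c[self.exog_names.index(name)] = 1.0
        return self.contrast(c, value=value, alpha=alpha)

    def summary(self) -> str:
        lines = [
            "Random-intercept linear mixed model (REML)",
            f"  n obs: {self.model.nobs}   groups: {len(self.model.group_labels)}"
            f"   fixed params: {self.model.k_fe}",
            f"  var(group) = {self.sigma2_group:.6g}   var(resid) = {self.sigma2_resid:.6g}"
            + ("   [boundary]" if self.on_boundary else ""),
            f"  {'term':<22}{'coef':>12}{'se':>10}{'df':>8}{'p':>10}",
        ]
        for j, name in enumerate(self.exog_names):
            tt = self.t_test_param(name)
            lines.append(
                f"  {name:<22}{tt['estimate']:>12.4f}{tt['se']:>10.4f}"
                f"{tt['df']:>8.1f}{tt['p']:>10.4f}"
            )
        return "\n".join(lines)
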