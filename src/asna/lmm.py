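"""Gaussian linear models with one optional random intercept, fitted by REML.

The permutation-corrected coefficient test refits the same small model
hundreds to thousands of times (once per randomized data set), so the fitter
is written for speed on that shape of problem: profiled restricted likelihood
in the single variance ratio lambda = sigma_u^2 / sigma_e^2, with all
X-dependent cross-products precomputed and only the response changing
between refits.  For a grouping factor Z the covariance is
V = sigma_e^2 (I + lambda Z Z'), block diagonal per group, and each block
inverse has the closed Sherman-Morrison form, so one likelihood evaluation
costs O(k p^2) for k groups and p fixed effects.

The fit agrees with statsmodels MixedLM (REML) on the same data; that
agreement is asserted in the test suite.  When the variance ratio estimate
hits the zero boundary the model degrades gracefully to ordinary least
squares (a note is logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

logger = logging.getLogger("asna")

__all__ = ["ModelFit", "RandomInterceptModel"]


@dataclass
class ModelFit:
    """Coefficients and uncertainty of one fitted (mixed) linear model."""

    terms: list[str]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    t_statistics: np.ndarray
    residual_variance: float
    random_effect_variance: float | None = None
    random_effect_name: str | None = None
    formula: str = ""
    n_obs: int = 0

    def __post_init__(self):
        if not (len(self.terms) == len(self.coefficients)
                == len(self.standard_errors) == len(self.t_statistics)):
            raise ValueError("coefficient/SE/t vectors must have the same length")

    def coefficient(self, term: str) -> float:
        return float(self.coefficients[self.terms.index(term)])


class RandomInterceptModel:
    """y = X beta + u[group] + e, REML-profiled over the variance ratio.

    Construct once per design (X and grouping fixed), then call
    :meth:`fit` with as many responses as needed.
    """

    def __init__(self, X: np.ndarray, groups: np.ndarray | None = None,
                 terms: list[str] | None = None, formula: str = "",
                 group_name: str | None = None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("design matrix must be 2-D")
        n, p = X.shape
        if n <= p:
            raise ValueError("more parameters than observations")
        if np.linalg.matrix_rank(X) < p:
            raise ValueError("rank-deficient design matrix")
        self.X = X
        self.terms = terms if terms is not None else [f"x{k}" for k in range(p)]
        self.formula = formula
        self.group_name = group_name
        self.XtX = X.T @ X
        if groups is None:
            self.k = 0
        else:
            groups = np.asarray(groups)
            codes = {g: i for i, g in enumerate(dict.fromkeys(groups.tolist()))}
            idx = np.array([codes[g] for g in groups.tolist()])
            self.k = len(codes)
            self.group_idx = idx
            self.n_g = np.bincount(idx, minlength=self.k).astype(float)
            # S[g] = sum of X rows in group g
            S = np.zeros((self.k, p))
            np.add.at(S, idx, X)
            self.S = S

    # -- internals ---------------------------------------------------------

    def _cross_products(self, y: np.ndarray):
        Xty = self.X.T @ y
        yty = float(y @ y)
        if self.k:
            t = np.bincount(self.group_idx, weights=y, minlength=self.k)
        else:
            t = None
        return Xty, yty, t

    def _profiled(self, lam: float, Xty, yty, t):
        """Generalized cross-products and determinant terms at ratio ``lam``."""
        if self.k and lam > 0:
            c = lam / (1.0 + lam * self.n_g)
            A = self.XtX - self.S.T @ (c[:, None] * self.S)
            b = Xty - self.S.T @ (c * t)
            quad = yty - float(c @ (t * t))
            logdet_v = float(np.log1p(lam * self.n_g).sum())
        else:
            A, b, quad, logdet_v = self.XtX, Xty, yty, 0.0
        beta = np.linalg.solve(A, b)
        rss = quad - float(beta @ b)
        return A, beta, max(rss, 1e-300), logdet_v

    def _criterion(self, lam: float, Xty, yty, t) -> float:
        n, p = self.X.shape
        A, _, rss, logdet_v = self._profiled(lam, Xty, yty, t)
        sign, logdet_a = np.linalg.slogdet(A)
        if sign <= 0:
            return np.inf
        return (n - p) * np.log(rss) + logdet_v + logdet_a

    # -- public ------------------------------------------------------------

    def fit(self, y: np.ndarray) -> ModelFit:
        y = np.asarray(y, dtype=float)
        n, p = self.X.shape
        if len(y) != n:
            raise ValueError("response length does not match design")
        Xty, yty, t = self._cross_products(y)
        lam = 0.0
        if self.k:
            res = minimize_scalar(
                lambda u: self._criterion(np.exp(u), Xty, yty, t),
                bounds=(-12.0, 12.0), method="bounded",
                options={"xatol": 1e-4},
            )
            lam = float(np.exp(res.x))
            if self._criterion(0.0, Xty, yty, t) <= res.fun:
                lam = 0.0
            if lam < 1e-8:
                lam = 0.0
                logger.debug("random-intercept variance at zero boundary; OLS fallback")
        A, beta, rss, _ = self._profiled(lam, Xty, yty, t)
        sigma2_e = rss / (n - p)
        cov = np.linalg.inv(A) * sigma2_e
        se = np.sqrt(np.diag(cov))
        return ModelFit(
            terms=list(self.terms),
            coefficients=beta,
            standard_errors=se,
            t_statistics=beta / se,
            residual_variance=float(sigma2_e),
            random_effect_variance=float(lam * sigma2_e) if self.k else None,
            random_effect_name=self.group_name,
            formula=self.formula,
            n_obs=n,
        )

    def coefficient(self, y: np.ndarray, index: int) -> float:
        """Focal fixed-effect estimate only (fast path for permutation loops)."""
        y = np.asarray(y, dtype=float)
        Xty, yty, t = self._cross_products(y)
        lam = 0.0
        if self.k:
            res = minimize_scalar(
                lambda u: self._criterion(np.exp(u), Xty, yty, t),
                bounds=(-12.0, 12.0), method="bounded",
                options={"xatol": 1e-4},
            )
            lam = float(np.exp(res.x))
            if self._criterion(0.0, Xty, yty, t) <= res.fun:
                lam = 0.0
        _, beta, _, _ = self._profiled(lam, Xty, yty, t)
        return float(beta[index])
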