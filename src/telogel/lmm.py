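"""Linear mixed models with crossed random intercepts.

All mixed models in this package share one structure: a handful of fixed
effects plus crossed random intercepts (e.g. natal box, rearing box, genetic
father) with independent variances, and an i.i.d. residual:

    y = X b + sum_k Z_k u_k + e,   u_k ~ N(0, s2_k I),   e ~ N(0, s2 I).

This module fits that model by profiled (RE)ML.  Writing V = s2 (I + Z D Z')
with D the diagonal of variance ratios g_k = s2_k/s2, the Woodbury identity
reduces every likelihood evaluation to a Cholesky factorization of the
q x q matrix A = I + D^1/2 Z'Z D^1/2 (q = total number of random levels),
which is orders of magnitude cheaper than factorizing the n x n V when the
same model must be refitted thousands of times (all-subsets enumeration,
Monte Carlo calibration).  The profiled criterion is optimized over log
variance ratios, so zero variances are reached smoothly at the boundary.

Denominator degrees of freedom for single-coefficient tests use the
Satterthwaite approximation: df = 2 se^4 / Var(se^2), with Var(se^2)
obtained by the delta method from the numerically evaluated observed
information of the REML log-likelihood in the variance parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

_LOG_RATIO_BOUNDS = (-14.0, 12.0)
_ZERO_RATIO = 2e-6  # variance ratios at/below this are reported as zero


@dataclass
class RandomStructure:
    """Factor codes and level labels for the crossed random intercepts."""

    names: list[str]
    codes: list[np.ndarray]
    n_levels: list[int]

    @classmethod
    def from_frame(cls, data: pd.DataFrame, factors: list[str]) -> "RandomStructure":
        names, codes, n_levels = [], [], []
        for f in factors:
            c, levels = pd.factorize(data[f], sort=True)
            if (c < 0).any():
                raise ValueError(f"random factor {f!r} has missing values")
            names.append(f)
            codes.append(c.astype(np.intp))
            n_levels.append(len(levels))
        return cls(names, codes, n_levels)

    def indicator(self, n: int) -> np.ndarray:
        """Dense n x q incidence matrix, blocks in factor order."""
        q = int(np.sum(self.n_levels))
        Z = np.zeros((n, q))
        off = 0
        for c, m in zip(self.codes, self.n_levels):
            Z[np.arange(n), off + c] = 1.0
            off += m
        return Z

    def expand_ratios(self, ratios: np.ndarray) -> np.ndarray:
        return np.repeat(ratios, self.n_levels)


@dataclass
class LMMFit:
    """A fitted mixed model."""

    params: pd.Series
    bse: pd.Series
    vcomp: dict[str, float]
    scale: float
    loglik: float
    method: str
    n: int
    k_params: int
    converged: bool
    singular: bool
    _solver: "_ProfiledLMM" = field(repr=False, default=None)
    _ratios: np.ndarray = field(repr=False, default=None)

    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame({"estimate": self.params, "se": self.bse})

    def satterthwaite_df(self, term: str) -> float:
        """Satterthwaite denominator df for the test of one coefficient."""
        cache = self.__dict__.setdefault("_df_cache", {})
        if term not in cache:
            cache[term] = self._solver.satterthwaite_df(self._ratios, self.scale, term)
        return cache[term]

    def f_test(self, term: str) -> tuple[float, float, float]:
        """(F, denominator df, p) for H0: coefficient of ``term`` = 0."""
        f = float((self.params[term] / self.bse[term]) ** 2)
        df2 = self.satterthwaite_df(term)
        p = float(stats.f.sf(f, 1, df2))
        return f, df2, p

    def conf_int(self, term: str, level: float = 0.95) -> tuple[float, float]:
        """t-interval for one coefficient using Satterthwaite df."""
        df = self.satterthwaite_df(term)
        tq = stats.t.ppf(0.5 + level / 2, df)
        b, se = float(self.params[term]), float(self.bse[term])
        return b - tq * se, b + tq * se


class _ProfiledLMM:
    """Profiled (RE)ML criterion over log variance ratios."""

    def __init__(self, y: np.ndarray, X: np.ndarray, struct: RandomStructure):
        self.y = y
        self.X = X
        self.struct = struct
        self.n, self.p = X.shape
        Z = struct.indicator(self.n)
        self.q = Z.shape[1]
        self.ZtZ = Z.T @ Z
        self.ZtX = Z.T @ X
        self.Zty = Z.T @ y
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)

    def _core(self, ratios: np.ndarray, want_chol: bool = False):
        """Woodbury core quantities for variance ratios g (one per factor)."""
        from scipy.linalg import cho_factor, cho_solve

        s = np.sqrt(self.struct.expand_ratios(ratios))
        A = (s[:, None] * self.ZtZ) * s[None, :]
        A[np.diag_indices(self.q)] += 1.0
        c, low = cho_factor(A, lower=True, check_finite=False)
        logdetW = 2.0 * float(np.sum(np.log(np.diag(c))))
        SZtXy = s[:, None] * np.column_stack([self.ZtX, self.Zty])
        Ai = cho_solve((c, low), SZtXy, check_finite=False)
        cross = SZtXy.T @ Ai
        XtWiX = self.XtX - cross[:-1, :-1]
        XtWiy = self.Xty - cross[:-1, -1]
        ytWiy = self.yty - cross[-1, -1]
        if want_chol:
            return XtWiX, XtWiy, ytWiy, logdetW, (c, low), s
        return XtWiX, XtWiy, ytWiy, logdetW

    def _profile(self, ratios: np.ndarray, reml: bool):
        XtWiX, XtWiy, ytWiy, logdetW = self._core(ratios)
        beta = np.linalg.solve(XtWiX, XtWiy)
        rss = float(ytWiy - beta @ XtWiy)
        rss = max(rss, 1e-12)
        n, p = self.n, self.p
        if reml:
            scale = rss / (n - p)
            sign, logdetXtWiX = np.linalg.slogdet(XtWiX)
            ll = -0.5 * (
                (n - p) * np.log(2 * np.pi * scale)
                + logdetW
                + logdetXtWiX
                + (n - p)
            )
        else:
            scale = rss / n
            ll = -0.5 * (n * np.log(2 * np.pi * scale) + logdetW + n)
        return float(ll), beta, scale, XtWiX

    def neg_loglik(self, log_ratios: np.ndarray, reml: bool) -> float:
        try:
            ll, *_ = self._profile(np.exp(log_ratios), reml)
        except np.linalg.LinAlgError:
            return 1e10
        return -ll

    def neg_loglik_grad(self, log_ratios: np.ndarray, reml: bool):
        """Profiled negative log-likelihood and its gradient in log ratios.

        Uses the envelope theorem: beta and the profiled scale are at their
        optima, so only the explicit dependence on the ratios contributes.
        For each factor k (incidence Z_k, rows `blk` of the stacked Z):
          d logdet W        =  tr(Z_k' W^-1 Z_k)
          d RSS             = -|Z_k' W^-1 r|^2
          d logdet X'W^-1X  = -tr((X'W^-1X)^-1 G_k G_k'),  G_k = X'W^-1 Z_k.
        """
        from scipy.linalg import cho_solve, solve_triangular

        ratios = np.exp(log_ratios)
        try:
            XtWiX, XtWiy, ytWiy, logdetW, (c, low), s = self._core(
                ratios, want_chol=True
            )
            beta = np.linalg.solve(XtWiX, XtWiy)
        except np.linalg.LinAlgError:
            return 1e10, np.zeros_like(log_ratios)
        rss = max(float(ytWiy - beta @ XtWiy), 1e-12)
        n, p = self.n, self.p
        sign, logdetXtWiX = np.linalg.slogdet(XtWiX)
        if reml:
            scale = rss / (n - p)
            ll = -0.5 * (
                (n - p) * np.log(2 * np.pi * scale) + logdetW + logdetXtWiX + (n - p)
            )
        else:
            scale = rss / n
            ll = -0.5 * (n * np.log(2 * np.pi * scale) + logdetW + n)

        # shared pieces: Z'W^-1 Z = ZtZ - ZtZ S A^-1 S ZtZ, etc.
        SZtZ = s[:, None] * self.ZtZ
        Li = solve_triangular(c, SZtZ, lower=True, check_finite=False)  # L^-1 S Z'Z
        # Z'W^-1 r in q-space
        ZtWiy = self.Zty - SZtZ.T @ cho_solve((c, low), s * self.Zty, check_finite=False)
        ZtWiX = self.ZtX - SZtZ.T @ cho_solve(
            (c, low), s[:, None] * self.ZtX, check_finite=False
        )
        ZtWir = ZtWiy - ZtWiX @ beta
        XtWiX_inv = np.linalg.inv(XtWiX)

        grad = np.zeros(len(ratios))
        off = 0
        for k, m in enumerate(self.struct.n_levels):
            blk = slice(off, off + m)
            # tr(Z_k' W^-1 Z_k) = tr(ZtZ_kk) - |L^-1 S Z'Z_k|_F^2
            tr_w = float(np.trace(self.ZtZ[blk, blk])) - float(
                np.sum(Li[:, blk] ** 2)
            )
            d_rss = -float(np.sum(ZtWir[blk] ** 2))
            Gk = ZtWiX[blk, :]  # q_k x p  (= (X'W^-1 Z_k)')
            d_logdetX = -float(np.sum((Gk @ XtWiX_inv) * Gk))
            if reml:
                d = 0.5 * ((n - p) * d_rss / rss + tr_w + d_logdetX)
            else:
                d = 0.5 * (n * d_rss / rss + tr_w)
            grad[k] = d * ratios[k]  # chain rule to log scale
            off += m
        return -ll, grad

    def loglik_at(self, variances: np.ndarray, scale: float, reml: bool = True) -> float:
        """(RE)ML log-likelihood at explicit variance components (not profiled)."""
        scale = max(float(scale), 1e-12)
        ratios = np.clip(np.asarray(variances, dtype=float), 0.0, None) / scale
        XtWiX, XtWiy, ytWiy, logdetW = self._core(ratios)
        beta = np.linalg.solve(XtWiX, XtWiy)
        rss = float(ytWiy - beta @ XtWiy)
        n, p = self.n, self.p
        if reml:
            sign, logdetXtWiX = np.linalg.slogdet(XtWiX)
            return -0.5 * (
                (n - p) * np.log(2 * np.pi)
                + (n - p) * np.log(scale)
                + logdetW
                + logdetXtWiX
                + rss / scale
            )
        return -0.5 * (
            n * np.log(2 * np.pi) + n * np.log(scale) + logdetW + rss / scale
        )

    def cov_beta(self, variances: np.ndarray, scale: float) -> np.ndarray:
        scale = max(float(scale), 1e-12)
        ratios = np.clip(np.asarray(variances, dtype=float), 0.0, None) / scale
        XtWiX, *_ = self._core(ratios)
        return scale * np.linalg.inv(XtWiX)

    def satterthwaite_df(
        self, ratios: np.ndarray, scale: float, term_or_index
    ) -> float:
        j = term_or_index if isinstance(term_or_index, int) else self._term_index(term_or_index)
        theta = np.concatenate([np.asarray(ratios) * scale, [scale]])
        free = np.concatenate([np.asarray(ratios) > _ZERO_RATIO, [True]])
        idx = np.nonzero(free)[0]
        if len(idx) == 0:
            return float(self.n - self.p)

        def se2(th_free: np.ndarray) -> float:
            th = theta.copy()
            th[idx] = th_free
            return float(self.cov_beta(th[:-1], th[-1])[j, j])

        def ll(th_free: np.ndarray) -> float:
            th = theta.copy()
            th[idx] = th_free
            return self.loglik_at(th[:-1], th[-1], reml=True)

        t0 = theta[idx]
        h = np.maximum(1e-4 * np.abs(t0), 1e-7)
        m = len(idx)
        grad = np.zeros(m)
        for a in range(m):
            e = np.zeros(m)
            e[a] = h[a]
            grad[a] = (se2(t0 + e) - se2(t0 - e)) / (2 * h[a])
        H = np.zeros((m, m))
        f0 = ll(t0)
        for a in range(m):
            ea = np.zeros(m)
            ea[a] = h[a]
            H[a, a] = (ll(t0 + ea) + ll(t0 - ea) - 2 * f0) / h[a] ** 2
            for b in range(a + 1, m):
                eb = np.zeros(m)
                eb[b] = h[b]
                H[a, b] = H[b, a] = (
                    ll(t0 + ea + eb)
                    - ll(t0 + ea - eb)
                    - ll(t0 - ea + eb)
                    + ll(t0 - ea - eb)
                ) / (4 * h[a] * h[b])
        try:
            var_theta = np.linalg.inv(-H)
            denom = float(grad @ var_theta @ grad)
        except np.linalg.LinAlgError:
            denom = 0.0
        f_hat = se2(t0)
        if denom <= 0 or not np.isfinite(denom):
            return float(self.n - self.p)
        df = 2.0 * f_hat**2 / denom
        # clamp to a sane range; tiny curvature can inflate df past n
        return float(min(max(df, 1.0), self.n - self.p))

    def _term_index(self, term: str) -> int:
        raise KeyError(term)  # overwritten by fit_lmm with named columns


def fit_lmm(
    y,
    X: pd.DataFrame,
    data: pd.DataFrame | None = None,
    random_factors: list[str] | None = None,
    method: str = "REML",
) -> LMMFit:
    """Fit a crossed random-intercepts LMM by profiled (RE)ML.

    Parameters
    ----------
    y : array-like
        Response vector.
    X : DataFrame
        Fixed-effect design matrix (include the intercept column explicitly).
    data : DataFrame
        Frame holding the random-factor columns (may be X's parent frame).
    random_factors : list of str
        Column names of crossed random-intercept factors; empty list fits
        ordinary least squares within the same interface.
    method : "REML" or "ML"
        REML for variance-component inference, ML for likelihood comparisons
        across fixed-effect structures (AICc).

    The reported ``k_params`` counts fixed-effect coefficients plus one
    variance per random factor plus the residual variance, the convention
    used for small-sample AICc.
    """
    method = method.upper()
    if method not in ("REML", "ML"):
        raise ValueError("method must be 'REML' or 'ML'")
    yv = np.asarray(y, dtype=float)
    Xm = X.to_numpy(dtype=float)
    n, p = Xm.shape
    if n <= p:
        raise ValueError(f"n = {n} too small for {p} fixed-effect columns")
    rank = np.linalg.matrix_rank(Xm)
    if rank < p:
        raise ValueError(
            f"rank-deficient fixed design: rank {rank} < {p} columns "
            f"({list(X.columns)})"
        )
    factors = random_factors or []
    struct = RandomStructure.from_frame(data if data is not None else X, factors)
    solver = _ProfiledLMM(yv, Xm, struct)
    cols = list(X.columns)
    solver._term_index = lambda t: cols.index(t)  # type: ignore[method-assign]

    reml = method == "REML"
    K = len(factors)
    if K == 0:
        ll, beta, scale, XtWiX = solver._profile(np.empty(0), reml)
        ratios = np.empty(0)
        converged = True
    else:
        def run(start):
            return optimize.minimize(
                solver.neg_loglik_grad,
                start,
                args=(reml,),
                jac=True,
                method="L-BFGS-B",
                bounds=[_LOG_RATIO_BOUNDS] * K,
                options={"maxiter": 200},
            )

        best = run(np.full(K, np.log(0.3)))
        if not best.success or best.fun >= 1e9:
            retry = run(np.full(K, np.log(0.01)))
            if retry.fun < best.fun:
                best = retry
        ratios = np.exp(best.x)
        ratios[ratios <= _ZERO_RATIO] = 0.0
        converged = bool(best.success) or best.fun < 1e9
        ll, beta, scale, XtWiX = solver._profile(ratios, reml)
    cov = scale * np.linalg.inv(XtWiX)
    bse = np.sqrt(np.diag(cov))
    vcomp = {f: float(r * scale) for f, r in zip(factors, ratios)}
    singular = any(v == 0.0 for v in vcomp.values())
    if singular:
        warnings.warn(
            "singular fit: variance component(s) estimated at zero "
            f"({[f for f, v in vcomp.items() if v == 0.0]})"
        )
    return LMMFit(
        params=pd.Series(beta, index=cols),
        bse=pd.Series(bse, index=cols),
        vcomp=vcomp,
        scale=float(scale),
        loglik=float(ll),
        method=method,
        n=n,
        k_params=p + K + 1,
        converged=converged,
        singular=singular,
        _solver=solver,
        _ratios=ratios,
    )
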