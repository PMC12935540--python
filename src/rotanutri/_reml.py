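"""Restricted maximum likelihood for Gaussian mixed models with random intercepts.

Handles the structure used throughout the package: ``y = X b + sum_k Z_k u_k + e``
with ``u_k ~ N(0, s2_k I)`` for a small number of crossed/nested grouping
factors (site, group-in-site, calendar year) and ``e ~ N(0, s2 I)``.

The REML criterion is profiled over ``b`` and the residual variance and
optimised over the log variance ratios ``lam_k = s2_k / s2``.  All linear
algebra is pushed through the Woodbury identity, so each evaluation costs
``O(q^3)`` with ``q`` the total number of random-effect levels, independent
of the number of observations after a one-off computation of cross products.

Satterthwaite degrees of freedom for a contrast ``c'b`` follow the standard
recipe: ``df = 2 f^2 / (g' A g)`` with ``f = c' Cov(b) c``, ``g`` its
gradient with respect to the variance parameters and ``A`` the inverse
observed REML information, both obtained by finite differences.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg, optimize

_LOG2PI = float(np.log(2.0 * np.pi))


class ConvergenceError(RuntimeError):
    """REML optimisation failed; carries the optimizer result."""

    def __init__(self, message, result=None):
        super().__init__(message)
        self.result = result


class VarCompLMM:
    """REML fit of a variance-components linear mixed model.

    Parameters
    ----------
    X : ndarray (n, p)
        Fixed-effects design matrix (full column rank expected).
    y : ndarray (n,)
        Response.
    factors : dict[str, ndarray]
        Ordered mapping factor name -> integer level codes (0..q_k-1) of
        length n.  Each factor contributes one random-intercept variance.
    """

    #: variance ratios below this are reported as pinned at zero
    PIN_TOL = 1e-7

    def __init__(self, X: np.ndarray, y: np.ndarray, factors: dict):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be (n, p) and y (n,) with matching n")
        self.n, self.p = X.shape
        self.factor_names = list(factors)
        self.q_sizes = []
        blocks = []
        for name, codes in factors.items():
            codes = np.asarray(codes)
            if codes.shape != (self.n,):
                raise ValueError(f"factor {name!r} codes must have length n")
            q_k = int(codes.max()) + 1
            self.q_sizes.append(q_k)
            Zk = np.zeros((self.n, q_k))
            Zk[np.arange(self.n), codes] = 1.0
            blocks.append(Zk)
        Z = np.hstack(blocks) if blocks else np.zeros((self.n, 0))
        self.q = Z.shape[1]
        self._col_factor = np.repeat(np.arange(len(self.q_sizes)), self.q_sizes)
        # one-off cross products; everything after is O(q^3)
        self._ZtZ = Z.T @ Z
        self._ZtX = Z.T @ X
        self._Zty = Z.T @ y
        self._XtX = X.T @ X
        self._Xty = X.T @ y
        self._yty = float(y @ y)
        self._X = X
        self._Z = Z
        self._y = y

    # -- profiled REML pieces ------------------------------------------------

    def _pieces(self, lams: np.ndarray) -> dict:
        """GLS quantities for V0 = I + Z diag(d) Z' with d = lams per column."""
        lams = np.asarray(lams, dtype=float)
        if np.any(lams < 0):
            raise ValueError("variance ratios must be >= 0")
        d = lams[self._col_factor] if self.q else np.zeros(0)
        sq = np.sqrt(d)
        W = np.eye(self.q) + (sq[:, None] * self._ZtZ) * sq[None, :]
        Lw = linalg.cholesky(W, lower=True)
        Ax = linalg.solve_triangular(Lw, sq[:, None] * self._ZtX, lower=True)
        Ay = linalg.solve_triangular(Lw, sq * self._Zty, lower=True)
        XtViX = self._XtX - Ax.T @ Ax
        XtViy = self._Xty - Ax.T @ Ay
        ytViy = self._yty - float(Ay @ Ay)
        Lx = linalg.cholesky(XtViX, lower=True)
        beta = linalg.cho_solve((Lx, True), XtViy)
        ssr = max(ytViy - float(XtViy @ beta), 0.0)
        logdetV0 = 2.0 * float(np.sum(np.log(np.diag(Lw))))
        logdetXtViX = 2.0 * float(np.sum(np.log(np.diag(Lx))))
        return {
            "beta": beta,
            "XtViX": XtViX,
            "Lx": Lx,
            "ssr": ssr,
            "logdetV0": logdetV0,
            "logdetXtViX": logdetXtViX,
        }

    def _crit(self, loglams: np.ndarray) -> float:
        """Profiled REML criterion (-2 log restricted likelihood, up to const)."""
        pc = self._pieces(np.exp(loglams))
        nmp = self.n - self.p
        sigma2 = max(pc["ssr"] / nmp, 1e-300)
        return nmp * np.log(sigma2) + pc["logdetV0"] + pc["logdetXtViX"]

    def fit(self) -> "VarCompLMM":
        x0 = np.zeros(len(self.q_sizes))
        res = optimize.minimize(
            self._crit,
            x0,
            method="L-BFGS-B",
            bounds=[(-30.0, 15.0)] * len(x0),
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9},
        )
        # polish: the numeric-gradient L-BFGS step stops slightly short of the
        # optimum; a derivative-free refinement pins the last few digits down
        alt = optimize.minimize(
            self._crit, res.x, method="Nelder-Mead",
            options={"maxiter": 2000, "xatol": 1e-10, "fatol": 1e-13},
        )
        if alt.fun <= res.fun:
            res = alt
        if not np.isfinite(res.fun):
            raise ConvergenceError("REML optimisation did not converge", res)
        self.converged_ = bool(res.success)
        self.opt_result_ = res
        lams = np.exp(res.x)
        lams[lams < self.PIN_TOL] = 0.0
        self.lams_ = lams
        self.pinned_ = lams == 0.0
        pc = self._pieces(lams)
        nmp = self.n - self.p
        self.sigma2_ = max(pc["ssr"] / nmp, 1e-300)
        self.beta_ = pc["beta"]
        Lx = pc["Lx"]
        XtViX_inv = linalg.cho_solve((Lx, True), np.eye(self.p))
        self.cov_beta_ = self.sigma2_ * XtViX_inv
        self.cov_beta_ = 0.5 * (self.cov_beta_ + self.cov_beta_.T)
        self.vc_ = {
            name: float(l * self.sigma2_)
            for name, l in zip(self.factor_names, lams)
        }
        self.loglik_ = self._loglik_phi(self._phi())
        # a numerically perfect fit leaves no information about the variance
        # parameters; derivative-based inference is then skipped
        self.degenerate_ = self.sigma2_ < 1e-12 * (self._yty / self.n + 1.0)
        self._dcov_cache = None
        self._phi_cov_cache = None
        return self

    # -- variance-parameter inference ---------------------------------------

    def _phi(self) -> np.ndarray:
        """Variance parameters (vc_1..vc_K, sigma2)."""
        return np.array([self.vc_[n] for n in self.factor_names] + [self.sigma2_])

    def _loglik_phi(self, phi: np.ndarray) -> float:
        """Full REML log likelihood at variance parameters phi."""
        phi = np.asarray(phi, dtype=float)
        sigma2 = phi[-1]
        if sigma2 <= 0 or np.any(phi[:-1] < 0):
            return -np.inf
        try:
            pc = self._pieces(np.minimum(phi[:-1] / sigma2, 1e12))
        except linalg.LinAlgError:
            return -np.inf
        nmp = self.n - self.p
        return -0.5 * (
            nmp * _LOG2PI
            + nmp * np.log(sigma2)
            + pc["logdetV0"]
            + pc["logdetXtViX"]
            + pc["ssr"] / sigma2
        )

    def _cov_beta_phi(self, phi: np.ndarray) -> np.ndarray:
        sigma2 = phi[-1]
        pc = self._pieces(np.maximum(phi[:-1], 0.0) / sigma2)
        return sigma2 * linalg.cho_solve((pc["Lx"], True), np.eye(self.p))

    def _free_idx(self) -> np.ndarray:
        """Indices of variance parameters not pinned at the zero boundary."""
        free = [k for k in range(len(self.factor_names)) if not self.pinned_[k]]
        return np.array(free + [len(self.factor_names)], dtype=int)

    def _steps(self, phi, idx):
        return np.array(
            [1e-4 * max(abs(phi[i]), 1e-3 * self.sigma2_, 1e-8) for i in idx]
        )

    def phi_cov(self) -> tuple:
        """Covariance of the free variance parameters from the REML information.

        Returns ``(A, idx)``: the inverse negative Hessian of the REML log
        likelihood over the free parameters, and their indices.  Components
        pinned at zero are held fixed.
        """
        if self._phi_cov_cache is not None:
            return self._phi_cov_cache
        phi = self._phi()
        idx = self._free_idx()
        if self.degenerate_:
            self._phi_cov_cache = (np.zeros((len(idx), len(idx))), idx)
            return self._phi_cov_cache
        h = self._steps(phi, idx)
        m = len(idx)
        H = np.zeros((m, m))

        def ll(shifts):
            p = phi.copy()
            p[idx] = np.maximum(p[idx] + shifts, 1e-12 * self.sigma2_)
            return self._loglik_phi(p)

        f0 = ll(np.zeros(m))
        for a in range(m):
            ea = np.zeros(m); ea[a] = h[a]
            H[a, a] = (ll(ea) - 2.0 * f0 + ll(-ea)) / h[a] ** 2
            for b in range(a + 1, m):
                eb = np.zeros(m); eb[b] = h[b]
                H[a, b] = H[b, a] = (
                    ll(ea + eb) - ll(ea - eb) - ll(-ea + eb) + ll(-ea - eb)
                ) / (4.0 * h[a] * h[b])
        info = -H
        if not np.all(np.isfinite(info)):
            # degenerate fit (e.g. zero residual variance): no curvature info
            A = np.zeros((m, m))
            self._phi_cov_cache = (A, idx)
            return A, idx
        try:
            A = linalg.inv(info)
        except (linalg.LinAlgError, ValueError):
            A = linalg.pinv(info)
        # guard against a non-PSD numerical Hessian
        w, V = linalg.eigh(0.5 * (A + A.T))
        A = (V * np.clip(w, 0.0, None)) @ V.T
        self._phi_cov_cache = (A, idx)
        return A, idx

    def _dcov_dphi(self) -> list:
        """d Cov(beta) / d phi_i for each free parameter, by central differences."""
        if self._dcov_cache is not None:
            return self._dcov_cache
        phi = self._phi()
        idx = self._free_idx()
        h = self._steps(phi, idx)
        grads = []
        for a, i in enumerate(idx):
            hp = phi.copy(); hp[i] += h[a]
            hm = phi.copy(); hm[i] = max(hm[i] - h[a], 1e-12 * self.sigma2_)
            step = hp[i] - hm[i]
            grads.append((self._cov_beta_phi(hp) - self._cov_beta_phi(hm)) / step)
        self._dcov_cache = grads
        return grads

    def satterthwaite(self, c: np.ndarray) -> tuple:
        """Standard error and Satterthwaite df of the contrast ``c' beta``."""
        c = np.asarray(c, dtype=float)
        f = float(c @ self.cov_beta_ @ c)
        se = np.sqrt(max(f, 0.0))
        if self.degenerate_:
            return se, float(self.n - self.p)
        A, _ = self.phi_cov()
        g = np.array([float(c @ D @ c) for D in self._dcov_dphi()])
        denom = float(g @ A @ g)
        nmp = self.n - self.p
        if denom <= 0 or f <= 0:
            return se, float(nmp)
        df = 2.0 * f * f / denom
        return se, float(np.clip(df, 1.0, nmp))
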