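"""Satterthwaite denominator degrees of freedom for linear mixed models.

statsmodels fits the mixed model but reports only asymptotic (z / Wald
chi-square) inference for the fixed effects.  At this study's size
(37 participants) that is anticonservative, so Wald tests here use
F / t references with Satterthwaite-approximated denominator df.

For a contrast c of the fixed effects, with variance parameters
θ = (vech(G), σ²) and fixed-effect covariance Σβ(θ) = (Σᵢ XᵢᵀVᵢ⁻¹Xᵢ)⁻¹,
Vᵢ = ZᵢGZᵢᵀ + σ²I, the df is

    ν(c) = 2 f(θ̂)² / (∇f ᵀ Var(θ̂) ∇f),    f(θ) = cᵀ Σβ(θ) c,

with Var(θ̂) the inverse curvature of the REML criterion at θ̂ and ∇f by
central differences.  Multi-df terms combine per-eigenvector dfs as in
lmerTest: with L (q×p), M = L Σβ Lᵀ = U D Uᵀ, each row of D^{-1/2}UᵀL
yields a 1-df ν_m; E = Σ_{ν_m>2} ν_m/(ν_m−2) and ddf = 2E/(E−q).

All computations here are REML-based and independent of the statsmodels
optimizer; the fitted (G, σ²) are taken as given.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from statsmodels.tools.numdiff import approx_hess3

__all__ = ["VarianceStructure", "SatterthwaiteEngine"]


@dataclass(frozen=True)
class VarianceStructure:
    """Which elements of the RE covariance G are free parameters."""

    k: int  # dimension of G
    kind: str  # "unstructured" | "diagonal"

    def pack(self, G: np.ndarray, scale: float) -> np.ndarray:
        if self.kind == "unstructured":
            idx = np.tril_indices(self.k)
            return np.concatenate([G[idx], [scale]])
        return np.concatenate([np.diag(G), [scale]])

    def unpack(self, theta: np.ndarray) -> tuple[np.ndarray, float]:
        G = np.zeros((self.k, self.k))
        if self.kind == "unstructured":
            idx = np.tril_indices(self.k)
            G[idx] = theta[:-1]
            G = G + np.tril(G, -1).T
        else:
            np.fill_diagonal(G, theta[:-1])
        return G, float(theta[-1])

    @property
    def n_params(self) -> int:
        return (self.k * (self.k + 1) // 2 if self.kind == "unstructured" else self.k) + 1


class SatterthwaiteEngine:
    """REML curvature and contrast-variance derivatives for one fitted model.

    Parameters
    ----------
    y, X : response and fixed-effects design (N, N×p).
    Z : random-effects design (N×k), shared column layout across groups.
    group_rows : per-group row-index arrays.
    G, scale : fitted RE covariance and residual variance.
    structure : which elements of G were free in the fit.
    """

    def __init__(
        self,
        y: np.ndarray,
        X: np.ndarray,
        Z: np.ndarray,
        group_rows: Sequence[np.ndarray],
        G: np.ndarray,
        scale: float,
        structure: VarianceStructure,
    ) -> None:
        self.y = np.asarray(y, float)
        self.X = np.asarray(X, float)
        Z = np.asarray(Z, float)
        # groups sharing a Z block (e.g. balanced designs) share V and its
        # Cholesky factor; batch them into one stacked triangular solve
        patterns: dict[bytes, list] = {}
        for rows in group_rows:
            patterns.setdefault(Z[rows].tobytes(), []).append(rows)
        self.patterns = []
        p = self.X.shape[1]
        for key, rowlist in patterns.items():
            Zp = Z[rowlist[0]]
            stacked = np.concatenate(
                [np.column_stack([self.X[r], self.y[r]]) for r in rowlist], axis=1
            )  # n_i × (p+1)·g
            self.patterns.append((Zp, stacked, len(rowlist), p))
        self.structure = structure
        self.theta_hat = structure.pack(np.asarray(G, float), float(scale))
        self._vartheta: np.ndarray | None = None
        self._sigma_cache: dict[bytes, np.ndarray] = {}
        self._perturbed: list[tuple[np.ndarray, np.ndarray]] | None = None
        self._h = np.maximum(1e-4, 1e-3 * np.abs(self.theta_hat))

    # ---- REML criterion -------------------------------------------------

    def _decompose(self, theta: np.ndarray):
        from scipy.linalg import cholesky, solve_triangular

        G, scale = self.structure.unpack(theta)
        p = self.X.shape[1]
        XtVX = np.zeros((p, p))
        XtVy = np.zeros(p)
        ytVy = 0.0
        logdet = 0.0
        for Zp, stacked, g, p in self.patterns:
            n = len(Zp)
            Vi = Zp @ G @ Zp.T + scale * np.eye(n)
            try:
                L = cholesky(Vi, lower=True, check_finite=False)
            except np.linalg.LinAlgError:
                L = cholesky(Vi + 1e-10 * np.eye(n), lower=True, check_finite=False)
            logdet += g * 2.0 * np.log(np.diag(L)).sum()
            W = solve_triangular(L, stacked, lower=True, check_finite=False)
            W = W.reshape(n, g, p + 1)
            Wx, wy = W[:, :, :p], W[:, :, p]
            XtVX += np.einsum("ngp,ngq->pq", Wx, Wx, optimize=True)
            XtVy += np.einsum("ngp,ng->p", Wx, wy, optimize=True)
            ytVy += float((wy**2).sum())
        return XtVX, XtVy, ytVy, logdet

    def neg_reml(self, theta: np.ndarray) -> float:
        """Negative REML log-likelihood (up to an additive constant)."""
        if theta[-1] <= 0:
            return np.inf
        XtVX, XtVy, ytVy, logdet = self._decompose(theta)
        sign, logdet_xvx = np.linalg.slogdet(XtVX)
        if sign <= 0:
            return np.inf
        beta = np.linalg.solve(XtVX, XtVy)
        rss = ytVy - XtVy @ beta
        return 0.5 * (logdet + logdet_xvx + rss)

    def fe_cov(self, theta: np.ndarray) -> np.ndarray:
        """Fixed-effect covariance Σβ(θ)."""
        key = theta.tobytes()
        if key not in self._sigma_cache:
            XtVX, *_ = self._decompose(theta)
            self._sigma_cache[key] = np.linalg.inv(XtVX)
        return self._sigma_cache[key]

    # ---- Satterthwaite --------------------------------------------------

    @property
    def var_theta(self) -> np.ndarray:
        """Approximate covariance of θ̂: inverse REML curvature (pinv at
        boundary fits where the Hessian is singular)."""
        if self._vartheta is None:
            H = approx_hess3(self.theta_hat, self.neg_reml)
            H = 0.5 * (H + H.T)
            self._vartheta = np.linalg.pinv(H, rcond=1e-10)
        return self._vartheta

    def _sigma_perturbed(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """Σβ at θ̂ ± h eⱼ for every variance parameter (computed once)."""
        if self._perturbed is None:
            out = []
            for j in range(len(self.theta_hat)):
                tp = self.theta_hat.copy()
                tm = self.theta_hat.copy()
                tp[j] += self._h[j]
                tm[j] -= self._h[j]
                if tm[-1] <= 0:
                    tm[-1] = self.theta_hat[-1]  # one-sided at the boundary
                out.append((self.fe_cov(tp), self.fe_cov(tm)))
            self._perturbed = out
        return self._perturbed

    def contrast_df(self, c: np.ndarray) -> float:
        """Satterthwaite df for a single contrast vector c."""
        c = np.asarray(c, float).ravel()
        f0 = float(c @ self.fe_cov(self.theta_hat) @ c)
        grad = np.empty(len(self.theta_hat))
        for j, (sp, sm) in enumerate(self._sigma_perturbed()):
            grad[j] = (c @ sp @ c - c @ sm @ c) / (2.0 * self._h[j])
        denom = float(grad @ self.var_theta @ grad)
        n_obs = len(self.y)
        if denom <= 0 or not np.isfinite(denom):
            return float(n_obs)
        return float(np.clip(2.0 * f0 * f0 / denom, 1.0, n_obs))

    def term_df(self, L: np.ndarray) -> float:
        """Denominator df for a q-df Wald F test of Lβ = 0 (lmerTest method)."""
        L = np.atleast_2d(np.asarray(L, float))
        q = L.shape[0]
        M = L @ self.fe_cov(self.theta_hat) @ L.T
        if q == 1:
            return self.contrast_df(L[0])
        vals, vecs = np.linalg.eigh(M)
        vals = np.maximum(vals, 1e-12)
        nus = []
        for m in range(q):
            c = (vecs[:, m] @ L) / np.sqrt(vals[m])
            nus.append(self.contrast_df(c))
        nus = np.asarray(nus)
        ok = nus > 2.0
        if not ok.any():
            return 2.0
        E = float((nus[ok] / (nus[ok] - 2.0)).sum())
        if E <= q:
            return float(len(self.y))
        return float(np.clip(2.0 * E / (E - q), 1.0, len(self.y)))
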