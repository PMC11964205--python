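"""Kenward-Roger small-sample inference for linear mixed models.

The Wald F test with the asymptotic fixed-effect covariance is
anticonservative at a few dozen participants.  The Kenward-Roger
procedure corrects this twice over: it inflates the fixed-effect
covariance Φ = (XᵀV⁻¹X)⁻¹ for the uncertainty of the estimated variance
parameters, and it derives a denominator df and an F scale factor by
matching the first two moments of the scaled Wald statistic.

The model covariance here is linear in its parameters,
V(θ) = Σ_r θ_r V_r (entries of the random-effect covariance G and the
residual variance), which makes every ingredient available in closed
form:

* P_r = −XᵀV⁻¹V_rV⁻¹X,  Q_rs = XᵀV⁻¹V_rV⁻¹V_sV⁻¹X,
* the expected REML information
  I_rs = ½[tr(V⁻¹V_rV⁻¹V_s) − 2 tr(ΦQ_rs) + tr(ΦP_rΦP_s)],  W = I⁻¹,
* Φ_A = Φ + 2Φ[Σ_rs W_rs (Q_rs − P_rΦP_s)]Φ,
* for a hypothesis L (q×p): A1, A2 moments built from Θ = Lᵀ(LΦLᵀ)⁻¹L,
  giving the denominator df and the scale on the Φ_A-based Wald/q.

All N×N algebra is block-diagonal by participant and batched over
participants that share a random-effect design block.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .satterthwaite import VarianceStructure

__all__ = ["KenwardRogerEngine"]


def _basis_matrices(structure: VarianceStructure) -> list[tuple[int, int] | None]:
    """Free-parameter index layout: (a, b) entries of G, then None for σ²."""
    k = structure.k
    if structure.kind == "unstructured":
        pairs = [(a, b) for a in range(k) for b in range(a + 1)]
    else:
        pairs = [(a, a) for a in range(k)]
    return pairs + [None]


class KenwardRogerEngine:
    """Adjusted covariance and KR F/t tests for one fitted mixed model."""

    def __init__(self, y, X, Z, group_rows, G, scale, structure: VarianceStructure):
        X = np.asarray(X, float)
        Z = np.asarray(Z, float)
        G = np.atleast_2d(np.asarray(G, float))
        self.p = X.shape[1]
        self.n_obs = len(X)
        basis = _basis_matrices(structure)
        m = len(basis)

        patterns: dict[bytes, list] = {}
        for rows in group_rows:
            patterns.setdefault(Z[rows].tobytes(), []).append(rows)

        phi_inv = np.zeros((self.p, self.p))
        PP = np.zeros((m, self.p, self.p))
        QQ = np.zeros((m, m, self.p, self.p))
        ktrace = np.zeros((m, m))
        for key, rowlist in patterns.items():
            Zp = Z[rowlist[0]]
            n = len(Zp)
            g = len(rowlist)
            Xst = np.concatenate([X[r] for r in rowlist], axis=1)  # n × g·p
            V = Zp @ G @ Zp.T + scale * np.eye(n)
            Vinv = np.linalg.inv(V)
            T = Vinv @ Xst
            T_ = T.reshape(n, g, self.p)
            X_ = Xst.reshape(n, g, self.p)
            phi_inv += np.einsum("ngp,ngq->pq", X_, T_, optimize=True)
            # derivative blocks V_r on this pattern
            Vr = np.empty((m, n, n))
            for r, pair in enumerate(basis):
                if pair is None:
                    Vr[r] = np.eye(n)
                else:
                    a, b = pair
                    E = np.zeros_like(G)
                    E[a, b] = E[b, a] = 1.0
                    Vr[r] = Zp @ E @ Zp.T
            H = Vr @ Vinv  # m × n × n
            O = np.einsum("rij,jk->rik", Vr, T, optimize=True)  # V_r V⁻¹ X
            VinvO = np.einsum("ij,rjk->rik", Vinv, O, optimize=True)
            O_ = O.reshape(m, n, g, self.p)
            VinvO_ = VinvO.reshape(m, n, g, self.p)
            PP -= np.einsum("rngp,ngq->rpq", O_, T_, optimize=True)
            QQ += np.einsum("rngp,sngq->rspq", O_, VinvO_, optimize=True)
            ktrace += g * np.einsum("rij,sji->rs", H, H, optimize=True)

        self.phi = np.linalg.inv(phi_inv)
        self.PP = PP
        self.QQ = QQ

        IE2 = np.empty((m, m))
        for r in range(m):
            phiP_r = self.phi @ PP[r]
            for s in range(r, m):
                IE2[r, s] = IE2[s, r] = (
                    ktrace[r, s]
                    - 2.0 * float(np.sum(self.phi * QQ[r, s]))
                    + float(np.sum(phiP_r * (PP[s] @ self.phi)))
                )
        eig = np.linalg.eigvalsh(IE2)
        if np.min(np.abs(eig)) > 1e-10:
            self.W = 2.0 * np.linalg.inv(IE2)
        else:  # boundary fit: variance parameter at zero
            self.W = 2.0 * np.linalg.pinv(IE2, rcond=1e-10)

        U = np.zeros((self.p, self.p))
        for r in range(m):
            for s in range(m):
                U += self.W[r, s] * (QQ[r, s] - PP[r] @ self.phi @ PP[s])
        self.phi_adj = self.phi + 2.0 * self.phi @ U @ self.phi

    # ------------------------------------------------------------------

    def _moments(self, L: np.ndarray) -> tuple[float, float, int]:
        L = np.atleast_2d(np.asarray(L, float))
        q = L.shape[0]
        theta = L.T @ np.linalg.solve(L @ self.phi @ L.T, L)
        TP = theta @ self.phi
        m = self.PP.shape[0]
        u = np.einsum("ij,rjk,kl->ril", TP, self.PP, self.phi, optimize=True)
        tr_u = np.trace(u, axis1=1, axis2=2)
        A1 = float(tr_u @ self.W @ tr_u)
        A2 = float(
            np.einsum("rij,rs,sji->", u, self.W, u, optimize=True)
        )
        return A1, A2, q

    def _df_scale(self, A1: float, A2: float, q: int) -> tuple[float, float]:
        B = (A1 + 6.0 * A2) / (2.0 * q)
        g = ((q + 1) * A1 - (q + 4) * A2) / ((q + 2) * A2) if A2 != 0 else 0.0
        denom = 3.0 * q + 2.0 * (1.0 - g)
        c1, c2, c3 = g / denom, (q - g) / denom, (q + 2 - g) / denom
        V0 = 1.0 + c1 * B
        V1 = 1.0 - c2 * B
        V2 = 1.0 - c3 * B
        if abs(V0) < 1e-10:
            V0 = 0.0
        base = (1.0 - A2 / q) / V1 if V1 != 0 else 1.0
        rho = (base**2) * V0 / V2 / q
        df2 = 4.0 + (q + 2.0) / (q * rho - 1.0) if q * rho > 1.0 else float(self.n_obs)
        df2 = float(np.clip(df2, 1.0, self.n_obs))
        scale = 1.0 if abs(df2 - 2.0) < 0.01 else df2 * (1.0 - A2 / q) / (df2 - 2.0)
        return df2, scale

    def test_term(self, L: np.ndarray, beta: np.ndarray):
        """Scaled Wald F test of Lβ = 0: returns (F, df1, df2, p)."""
        L = np.atleast_2d(np.asarray(L, float))
        A1, A2, q = self._moments(L)
        df2, scale = self._df_scale(A1, A2, q)
        est = L @ beta
        wald = float(est @ np.linalg.solve(L @ self.phi_adj @ L.T, est))
        F = scale * wald / q
        return F, q, df2, float(stats.f.sf(F, q, df2))

    def test_contrast(self, c: np.ndarray, beta: np.ndarray):
        """t test of cᵀβ = 0 with the adjusted covariance and KR df.

        Returns (estimate, se, df, t, p)."""
        c = np.asarray(c, float).ravel()
        A1, A2, q = self._moments(c[None, :])
        df, _ = self._df_scale(A1, A2, q)
        est = float(c @ beta)
        se = float(np.sqrt(c @ self.phi_adj @ c))
        t = est / se
        return est, se, df, t, float(2.0 * stats.t.sf(abs(t), df))
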