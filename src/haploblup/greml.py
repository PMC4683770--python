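"""EM-algorithm REML estimation of the variance components.

Both formulations iterate multiplicative, nonnegativity-preserving updates
toward the REML stationary point:

* CE route:   sigma2_i <- sigma2_i * y'P Z S_i Z' P y / tr(P Z S_i Z')
              sigma2_e <- sigma2_e * y'P P y / tr(P)
* QM route:   sigma2_i <- tau_hat_i' tau_hat_i / [t_i - tr(C^ii) lambda_i]
              sigma2_e <- e_hat' e_hat / {N - [r - sum_i tr(C^ii lambda_i)]}

where P is the REML projection of the phenotypic covariance V, C^ii are the
diagonal blocks of the inverse of the absorbed mixed-model coefficient
matrix H = Zg'M Zg + (+) lambda_i I (M the fixed-effect absorber), e_hat the
MME residual and r the numerical rank of the full MME coefficient matrix.
The two routes produce identical iterate sequences; EM is slow near the
boundary but never leaves the parameter space.

When there is a single genetic term and one record per individual the CE
iteration runs in the eigenbasis of its relationship matrix: one symmetric
eigendecomposition up front, O(q) work per iteration.  The fast path is
algebraically exact, not an approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
from sklearn.base import BaseEstimator

from .mixedmodel import ModelSpec, _PINV_RCOND, _solve_spd

__all__ = [
    "EMControl",
    "VarianceComponents",
    "EMREML",
    "em_reml_ce",
    "em_reml_qm",
    "heritabilities",
    "block_heritabilities",
]


@dataclass(frozen=True)
class EMControl:
    """Convergence controls for the EM iteration."""

    tol: float = 1e-8  # max relative change in any component
    max_iter: int = 10_000
    floor_frac: float = 1e-12  # component floor, fraction of var(y)


@dataclass
class VarianceComponents:
    """Estimated variance components with iteration history."""

    names: tuple[str, ...]
    sigma2: np.ndarray
    sigma2_e: float
    converged: bool
    iterations: int
    history: np.ndarray  # (iterations+1, n_terms+1), residual last
    loglik: np.ndarray | None = None  # REML log-likelihood per iteration

    @property
    def sigma2_y(self) -> float:
        return float(self.sigma2.sum() + self.sigma2_e)

    def as_dict(self) -> dict[str, float]:
        out = {n: float(s) for n, s in zip(self.names, self.sigma2)}
        out["residual"] = float(self.sigma2_e)
        return out


def _start_values(spec: ModelSpec, start) -> tuple[np.ndarray, float]:
    r = len(spec.terms)
    if start is None:
        vy = float(np.var(spec.y))
        if vy == 0:
            vy = 1.0
        return np.full(r, vy / (r + 1)), vy / (r + 1)
    sigma2 = np.asarray([start[t.name] for t in spec.terms], dtype=float)
    s2e = float(start["residual"])
    if np.any(sigma2 <= 0) or s2e <= 0:
        raise ValueError("starting values must be positive")
    return sigma2, s2e


def _reml_loglik(V, XtViX, yPy) -> float:
    sign, logdetV = np.linalg.slogdet(V)
    s2, logdetX = np.linalg.slogdet(XtViX)
    return -0.5 * (logdetV + logdetX + yPy)


def _em_ce_dense(spec: ModelSpec, sigma2, s2e, control) -> VarianceComponents:
    y, X, Z = spec.y, spec.X, spec.Zmat()
    N = spec.N
    ZSZ = [Z @ t.kernel() @ Z.T for t in spec.terms]
    floor = control.floor_frac * max(float(np.var(y)), np.finfo(float).tiny)
    history = [np.append(sigma2, s2e)]
    loglik = []
    converged = False
    it = 0
    for it in range(1, control.max_iter + 1):
        V = sum(s * M for s, M in zip(sigma2, ZSZ)) + s2e * np.eye(N)
        Vi = _solve_spd(V, np.eye(N))
        ViX = Vi @ X
        XtViX = X.T @ ViX
        P = Vi - ViX @ np.linalg.pinv(XtViX, rcond=_PINV_RCOND) @ ViX.T
        Py = P @ y
        loglik.append(_reml_loglik(V, XtViX, float(y @ Py)))
        new = np.empty_like(sigma2)
        for i, M in enumerate(ZSZ):
            new[i] = sigma2[i] * (Py @ M @ Py) / np.trace(P @ M)
        new_e = s2e * (Py @ Py) / np.trace(P)
        new = np.maximum(new, floor)
        new_e = max(new_e, floor)
        old = np.append(sigma2, s2e)
        sigma2, s2e = new, float(new_e)
        history.append(np.append(sigma2, s2e))
        rel = np.max(np.abs(history[-1] - old) / np.maximum(np.abs(old), floor))
        if rel < control.tol:
            converged = True
            break
    return VarianceComponents(
        names=tuple(t.name for t in spec.terms),
        sigma2=sigma2,
        sigma2_e=s2e,
        converged=converged,
        iterations=it,
        history=np.array(history),
        loglik=np.array(loglik),
    )


def _em_ce_eigen(spec: ModelSpec, sigma2, s2e, control) -> VarianceComponents:
    """Exact CE iteration in the eigenbasis of the single kernel S."""
    y, X = spec.y, spec.X
    term = spec.terms[0]
    lam_S, Q = np.linalg.eigh(term.kernel())
    lam_S = np.maximum(lam_S, 0.0)
    yt = Q.T @ y
    Xt = Q.T @ X
    floor = control.floor_frac * max(float(np.var(y)), np.finfo(float).tiny)
    history = [np.array([sigma2[0], s2e])]
    loglik = []
    converged = False
    it = 0
    s2 = float(sigma2[0])
    for it in range(1, control.max_iter + 1):
        d = 1.0 / (s2 * lam_S + s2e)
        DX = Xt * d[:, None]
        B = Xt.T @ DX
        Binv = np.linalg.pinv(B, rcond=_PINV_RCOND)
        Py = d * yt - DX @ (Binv @ (DX.T @ yt))
        yPy = float(yt @ Py)
        sign, logdetB = np.linalg.slogdet(B)
        loglik.append(-0.5 * (np.sum(np.log(s2 * lam_S + s2e)) + logdetB + yPy))
        trP = d.sum() - np.trace(Binv @ (DX.T @ DX))
        trPS = float(d @ lam_S) - np.trace(Binv @ (DX.T @ (lam_S[:, None] * DX)))
        new = s2 * float(Py @ (lam_S * Py)) / trPS
        new_e = s2e * float(Py @ Py) / trP
        new = max(new, floor)
        new_e = max(new_e, floor)
        old = np.array([s2, s2e])
        s2, s2e = float(new), float(new_e)
        history.append(np.array([s2, s2e]))
        rel = np.max(np.abs(history[-1] - old) / np.maximum(np.abs(old), floor))
        if rel < control.tol:
            converged = True
            break
    return VarianceComponents(
        names=(term.name,),
        sigma2=np.array([s2]),
        sigma2_e=s2e,
        converged=converged,
        iterations=it,
        history=np.array(history),
        loglik=np.array(loglik),
    )


def em_reml_ce(
    spec: ModelSpec,
    start: dict[str, float] | None = None,
    control: EMControl = EMControl(),
) -> VarianceComponents:
    """EM-REML through the phenotypic covariance (CE route).

    Accepts singular relationship matrices.  Returns the best iterate with
    ``converged=False`` when the iteration cap is hit.
    """
    sigma2, s2e = _start_values(spec, start)
    if len(spec.terms) == 1 and spec.Z is None:
        return _em_ce_eigen(spec, sigma2, s2e, control)
    return _em_ce_dense(spec, sigma2, s2e, control)


def em_reml_qm(
    spec: ModelSpec,
    start: dict[str, float] | None = None,
    control: EMControl = EMControl(),
) -> VarianceComponents:
    """EM-REML through the mixed-model equations (QM route).

    Iterates the effect-level updates; converges to the same stationary
    point (indeed the same iterate sequence) as the CE route.
    """
    for t in spec.terms:
        if t.T is None:
            raise ValueError(f"{t.name}: the QM route requires the T matrix")
    y, X, Z = spec.y, spec.X, spec.Zmat()
    N = spec.N
    Z_list = [Z @ t.T for t in spec.terms]
    Zg = np.hstack(Z_list)
    sizes = [T.shape[1] for T in Z_list]
    edges = np.concatenate([[0], np.cumsum(sizes)])
    c = X.shape[1]
    XtX_inv = np.linalg.pinv(X.T @ X, rcond=_PINV_RCOND)
    M = np.eye(N) - X @ XtX_inv @ X.T
    ZgM = Zg.T @ M
    ZgMZg = ZgM @ Zg
    ZgMy = ZgM @ y
    sigma2, s2e = _start_values(spec, start)
    floor = control.floor_frac * max(float(np.var(y)), np.finfo(float).tiny)
    history = [np.append(sigma2, s2e)]
    converged = False
    rank_C = None
    it = 0
    for it in range(1, control.max_iter + 1):
        lam = s2e / sigma2
        lam_diag = np.concatenate(
            [np.full(t, l) for t, l in zip(sizes, lam)]
        )
        H = ZgMZg + np.diag(lam_diag)
        try:  # H is positive definite for lambda > 0; pinv only as fallback
            c_low = sla.cho_factor(H, lower=True, check_finite=False)
            Hinv = sla.cho_solve(c_low, np.eye(H.shape[0]), check_finite=False)
        except np.linalg.LinAlgError:
            Hinv = np.linalg.pinv(H, rcond=_PINV_RCOND, hermitian=True)
        tau = Hinv @ ZgMy
        b_hat = XtX_inv @ (X.T @ (y - Zg @ tau))
        e_hat = y - X @ b_hat - Zg @ tau
        if rank_C is None:
            C = np.block(
                [[X.T @ X, X.T @ Zg], [Zg.T @ X, Zg.T @ Zg + np.diag(lam_diag)]]
            )
            rank_C = int(np.linalg.matrix_rank(C, tol=_PINV_RCOND * sla.norm(C, 2)))
        new = np.empty_like(sigma2)
        tr_Clam = 0.0
        for i, t in enumerate(sizes):
            blk = slice(edges[i], edges[i + 1])
            tr_Cii = float(np.trace(Hinv[blk, blk]))
            tr_Clam += tr_Cii * lam[i]
            tau_i = tau[blk]
            new[i] = float(tau_i @ tau_i) / (t - tr_Cii * lam[i])
        new_e = float(e_hat @ e_hat) / (N - (rank_C - tr_Clam))
        new = np.maximum(new, floor)
        new_e = max(new_e, floor)
        old = np.append(sigma2, s2e)
        sigma2, s2e = new, float(new_e)
        history.append(np.append(sigma2, s2e))
        rel = np.max(np.abs(history[-1] - old) / np.maximum(np.abs(old), floor))
        if rel < control.tol:
            converged = True
            break
    return VarianceComponents(
        names=tuple(t.name for t in spec.terms),
        sigma2=sigma2,
        sigma2_e=s2e,
        converged=converged,
        iterations=it,
        history=np.array(history),
    )


def heritabilities(vc: VarianceComponents) -> dict[str, float]:
    """Per-term heritabilities h2_i = sigma2_i / sigma2_y and their total H2."""
    s2y = vc.sigma2_y
    if s2y == 0:
        raise ValueError("phenotypic variance is zero")
    out = {n: float(s) / s2y for n, s in zip(vc.names, vc.sigma2)}
    out["H2"] = float(vc.sigma2.sum()) / s2y
    return out


def block_heritabilities(
    vc: VarianceComponents,
    tau_hat: dict[str, np.ndarray],
    block_slices: dict[str, dict[str, slice]],
) -> pd.DataFrame:
    """Per-block heritabilities h2_ij = (tau_ij'tau_ij / tau_i'tau_i) h2_i.

    ``block_slices`` maps each term name to its block-name -> column-slice
    mapping (the ``alpha_slices`` / ``delta_slices`` of the term's coding).
    Block shares of a term sum to the term heritability by construction.
    """
    h2 = heritabilities(vc)
    rows = []
    for term, slices in block_slices.items():
        tau = tau_hat[term]
        total = float(tau @ tau)
        for block, sl in slices.items():
            tau_j = tau[sl]
            share = float(tau_j @ tau_j) / total if total > 0 else 0.0
            rows.append(
                {"term": term, "block": block, "h2": share * h2[term]}
            )
    return pd.DataFrame(rows)


class EMREML(BaseEstimator):
    """EM-REML variance-component estimator.

    Parameters
    ----------
    method : {'auto', 'ce', 'qm'}
        'auto' picks CE when individuals are fewer than total effects,
        QM otherwise (the cheaper system in each regime).
    tol, max_iter, floor_frac : see EMControl.

    Attributes
    ----------
    sigma2_ : dict of term name -> estimate, residual included.
    h2_ : dict of per-term heritabilities plus total 'H2'.
    converged_, n_iter_, history_ : iteration diagnostics.
    """

    def __init__(
        self,
        method: str = "auto",
        tol: float = 1e-8,
        max_iter: int = 10_000,
        floor_frac: float = 1e-12,
    ):
        self.method = method
        self.tol = tol
        self.max_iter = max_iter
        self.floor_frac = floor_frac

    def fit(self, spec: ModelSpec, y=None, start: dict[str, float] | None = None):
        control = EMControl(
            tol=self.tol, max_iter=self.max_iter, floor_frac=self.floor_frac
        )
        method = self.method
        if method == "auto":
            n_eff = sum(
                t.T.shape[1] if t.T is not None else spec.q for t in spec.terms
            )
            method = "ce" if spec.q < spec.X.shape[1] + n_eff else "qm"
        if method == "ce":
            vc = em_reml_ce(spec, start=start, control=control)
        elif method == "qm":
            vc = em_reml_qm(spec, start=start, control=control)
        else:
            raise ValueError(f"unknown method {self.method!r}")
        self.components_ = vc
        self.method_ = method
        self.sigma2_ = vc.as_dict()
        self.h2_ = heritabilities(vc)
        self.converged_ = vc.converged
        self.n_iter_ = vc.iterations
        self.history_ = vc.history
        return self
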