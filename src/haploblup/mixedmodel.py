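"""GBLUP under two equivalent mixed-model formulations.

The model is  y = X b + Z (sum_i u_i) + e  with u_i = T_i tau_i,
Var(tau_i) = sigma2_i I, Var(u_i) = sigma2_i S_i where S_i = T_i T_i',
and Var(e) = sigma2_e I.

Two routes give identical predictions:

* conditional expectation (CE): works through V = Z(sum sigma2_i S_i)Z' +
  sigma2_e I and the projection P = V^-1 - V^-1 X (X'V^-1 X)^- X'V^-1;
  u_hat_i = sigma2_i S_i Z'Py = S_i eps_i.  Tolerates singular S_i and is
  cheapest when individuals are few.
* mixed-model equations (QM): solves the Henderson system at the effect
  level for (b_hat, tau_hat) with ridge blocks lambda_i = sigma2_e/sigma2_i,
  then u_hat_i = T_i tau_hat_i.  Cheapest when effects are fewer than
  individuals; no relationship-matrix inverse is ever formed.

Validation individuals are predicted from the training solutions:
u_hat_i0 = S_i01 eps_i (CE) or T_i0 tau_hat_i (QM).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla
from sklearn.base import BaseEstimator

__all__ = [
    "RandomTerm",
    "ModelSpec",
    "PredictionResult",
    "GBLUP",
    "gblup_ce",
    "gblup_qm",
    "predict_validation",
]

_PINV_RCOND = 1e-10


@dataclass
class RandomTerm:
    """One random genetic term: scaled coding matrix T and/or kernel S."""

    name: str
    sigma2: float
    T: np.ndarray | None = None  # q x t scaled coding matrix
    S: np.ndarray | None = None  # q x q relationship matrix (T T')

    def __post_init__(self):
        if self.sigma2 < 0:
            raise ValueError(f"{self.name}: sigma2 must be nonnegative")
        if self.T is None and self.S is None:
            raise ValueError(f"{self.name}: supply T or S (or both)")

    def kernel(self) -> np.ndarray:
        if self.S is None:
            self.S = self.T @ self.T.T
        return self.S


@dataclass
class ModelSpec:
    """Phenotypes, fixed effects, incidence, and random terms of one model."""

    y: np.ndarray
    terms: list[RandomTerm]
    sigma2_e: float
    X: np.ndarray | None = None  # defaults to an intercept column
    Z: np.ndarray | None = None  # defaults to identity (one record each)

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float).ravel()
        N = self.y.size
        if self.X is None:
            self.X = np.ones((N, 1))
        else:
            self.X = np.asarray(self.X, dtype=float)
            if self.X.shape[0] != N:
                raise ValueError("X row count must match y")
        if self.sigma2_e < 0:
            raise ValueError("sigma2_e must be nonnegative")
        if self.Z is not None:
            self.Z = np.asarray(self.Z, dtype=float)
            if self.Z.shape[0] != N:
                raise ValueError("Z row count must match y")
            rows = self.Z.sum(axis=1)
            if not (np.allclose(rows, 1) and np.isin(self.Z, (0, 1)).all()):
                raise ValueError("each Z row must have exactly one 1")

    @property
    def N(self) -> int:
        return self.y.size

    @property
    def q(self) -> int:
        if self.Z is not None:
            return self.Z.shape[1]
        t = self.terms[0]
        return t.T.shape[0] if t.T is not None else t.S.shape[0]

    def Zmat(self) -> np.ndarray:
        return np.eye(self.N) if self.Z is None else self.Z


@dataclass
class PredictionResult:
    """BLUE of fixed effects and GBLUP of every genetic-value type."""

    method: str
    b_hat: np.ndarray
    u_hat: dict[str, np.ndarray]
    g_hat: np.ndarray = field(init=False)
    epsilon: dict[str, np.ndarray] | None = None  # CE regressed phenotypes
    tau_hat: dict[str, np.ndarray] | None = None  # QM effect solutions

    def __post_init__(self):
        self.g_hat = np.sum(list(self.u_hat.values()), axis=0)


def _solve_spd(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    c, low = sla.cho_factor(A, lower=True, check_finite=False)
    return sla.cho_solve((c, low), B, check_finite=False)


def gblup_ce(spec: ModelSpec) -> PredictionResult:
    """GBLUP by conditional expectation (Model-I); accepts singular S_i."""
    y, X, Z = spec.y, spec.X, spec.Zmat()
    G = sum(t.sigma2 * t.kernel() for t in spec.terms)
    V = Z @ G @ Z.T + spec.sigma2_e * np.eye(spec.N)
    try:
        Vi_y = _solve_spd(V, y)
        Vi_X = _solve_spd(V, X)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "V is singular; a positive sigma2_e makes it invertible"
        ) from err
    XtViX = X.T @ Vi_X
    b_hat = np.linalg.pinv(XtViX, rcond=_PINV_RCOND) @ (X.T @ Vi_y)
    Py = Vi_y - Vi_X @ b_hat
    ZtPy = Z.T @ Py
    epsilon = {t.name: t.sigma2 * ZtPy for t in spec.terms}
    u_hat = {t.name: t.kernel() @ epsilon[t.name] for t in spec.terms}
    return PredictionResult(
        method="ce", b_hat=b_hat, u_hat=u_hat, epsilon=epsilon
    )


def gblup_qm(spec: ModelSpec) -> PredictionResult:
    """GBLUP by the mixed-model equations (Model-II); needs sigma2_i > 0."""
    y, X, Z = spec.y, spec.X, spec.Zmat()
    for t in spec.terms:
        if t.T is None:
            raise ValueError(f"{t.name}: the QM route requires the T matrix")
        if t.sigma2 <= 0:
            raise ValueError(
                f"{t.name}: sigma2 must be positive for QM; exclude the term"
            )
    Z_list = [Z @ t.T for t in spec.terms]
    Zg = np.hstack(Z_list)
    lam = np.concatenate(
        [np.full(t.T.shape[1], spec.sigma2_e / t.sigma2) for t in spec.terms]
    )
    c = X.shape[1]
    C = np.block([[X.T @ X, X.T @ Zg], [Zg.T @ X, Zg.T @ Zg + np.diag(lam)]])
    rhs = np.concatenate([X.T @ y, Zg.T @ y])
    sol = np.linalg.pinv(C, rcond=_PINV_RCOND, hermitian=True) @ rhs
    b_hat = sol[:c]
    tau = sol[c:]
    tau_hat, u_hat = {}, {}
    start = 0
    for t in spec.terms:
        ti = t.T.shape[1]
        tau_hat[t.name] = tau[start : start + ti]
        u_hat[t.name] = t.T @ tau_hat[t.name]
        start += ti
    return PredictionResult(
        method="qm", b_hat=b_hat, u_hat=u_hat, tau_hat=tau_hat
    )


def predict_validation(
    result: PredictionResult, cross: dict[str, np.ndarray]
) -> dict[str, np.ndarray]:
    """Genetic values of validation individuals from training solutions.

    ``cross`` maps each term name to S_i01 (q0 x q, CE route) or T_i0
    (q0 x t_i, QM route), built against the training catalog, frequencies
    and scale constant.  Returns per-term predictions plus their sum 'g'.
    """
    out: dict[str, np.ndarray] = {}
    for name, M in cross.items():
        if result.method == "ce":
            eps = result.epsilon[name]
            if M.shape[1] != eps.size:
                raise ValueError(f"{name}: S_01 must have q columns")
            out[name] = M @ eps
        else:
            tau = result.tau_hat[name]
            if M.shape[1] != tau.size:
                raise ValueError(f"{name}: T_0 must have t_i columns")
            out[name] = M @ tau
    out["g"] = np.sum([v for k, v in out.items() if k != "g"], axis=0)
    return out


class GBLUP(BaseEstimator):
    """Genomic best linear unbiased prediction estimator.

    Parameters
    ----------
    method : {'auto', 'ce', 'qm'}
        Computing route.  'auto' picks CE when the number of individuals is
        below the total effect count (plus fixed effects), QM otherwise —
        the cheaper system to factorize in each regime.

    Attributes
    ----------
    b_ : BLUE of the fixed effects.
    u_ : dict mapping term name to its predicted genetic values (training).
    g_ : total predicted genotypic values, sum of the terms.
    method_ : the route actually used.
    """

    def __init__(self, method: str = "auto"):
        self.method = method

    def _choose(self, spec: ModelSpec) -> str:
        if self.method in ("ce", "qm"):
            return self.method
        if self.method != "auto":
            raise ValueError(f"unknown method {self.method!r}")
        n_eff = sum(
            t.T.shape[1] if t.T is not None else spec.q for t in spec.terms
        )
        return "ce" if spec.q < spec.X.shape[1] + n_eff else "qm"

    def fit(self, spec: ModelSpec, y=None):
        method = self._choose(spec)
        result = gblup_ce(spec) if method == "ce" else gblup_qm(spec)
        self.result_ = result
        self.method_ = method
        self.b_ = result.b_hat
        self.u_ = result.u_hat
        self.g_ = result.g_hat
        return self

    def predict(self, cross: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        if not hasattr(self, "result_"):
            raise RuntimeError("GBLUP is not fitted")
        return predict_validation(self.result_, cross)
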