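"""Conditional prediction of an ongoing trial's random effects.

An ongoing trial N may have collected the surrogate on its subjects while
the true endpoint is still largely unobserved.  Because the model is
jointly multivariate normal, the trial's random-effect vector gamma_N has a
closed-form conditional law given whatever rows of data exist:

    gamma_N | Y_N ~ N(gamma_tilde, D_tilde)
    gamma_tilde = D W' V^{-1} (Y - M mu),   D_tilde = D - D W' V^{-1} W D,

with V = W D W' + R.  Missing true-endpoint values are handled exactly by
deleting their rows from (Y, M, W) and the corresponding rows/columns of R
— for a multivariate normal this *is* analytic marginalisation.

The implementation uses the algebraically identical precision form

    D_tilde = (D^{-1} + W' R^{-1} W)^{-1},
    gamma_tilde = D_tilde W' R^{-1} (Y - M mu),

which costs O(q^3 + n) instead of inverting the 2n x 2n matrix V; the
equivalence to the direct V-based formula is unit-tested.

Plugging the conditional law into the orthant formulas yields the
ongoing-trial measures psi_SP13_N(x) and psi_SP123_N(x): the conditional
mean of Delta_S(x) is beta_S + delta_S x + b_tilde_S (+ x d_tilde_S under
S2) and its covariance is the (1, x)-weighted quadratic form in the
(b, d) block of D_tilde.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .model import (
    ModelParams,
    Scenario,
    TreatmentEffectJoint,
    effect_weight_vectors,
)
from .measures import psi_sp13 as _psi13, psi_sp123 as _psi123

__all__ = [
    "DesignMatrices",
    "ConditionalEffects",
    "build_design_matrices",
    "conditional_random_effects",
    "conditional_effect_joint",
    "psi_sp13_partial",
    "psi_sp123_partial",
]

_R_FLOOR = 1e-8


@dataclass(frozen=True)
class DesignMatrices:
    """Stacked fixed/random design and residual covariance for one trial.

    Rows come in subject order, S row then T row, with the T row removed for
    subjects whose true endpoint is missing.
    """

    M: np.ndarray  # (m, n_fixed)
    W: np.ndarray  # (m, q)
    R: np.ndarray  # (m, m) block-diagonal residual covariance
    y: np.ndarray  # (m,) observed responses in the same row order

    @property
    def V(self) -> np.ndarray:
        """Marginal covariance W D W' + R requires D; see ``marginal_cov``."""
        raise AttributeError("use marginal_cov(D)")

    def marginal_cov(self, D: np.ndarray) -> np.ndarray:
        return self.W @ D @ self.W.T + self.R


@dataclass(frozen=True)
class ConditionalEffects:
    """Predicted random effects of the ongoing trial and their uncertainty."""

    gamma_tilde: np.ndarray
    D_tilde: np.ndarray


def _feature_rows(scenario: Scenario, n_cov: int, z: np.ndarray, x: np.ndarray):
    """Per-subject feature vectors for fixed (f) and random (g) designs."""
    n = z.shape[0]
    cols = [np.ones(n), z] + [x[:, k] for k in range(n_cov)] + [
        x[:, k] * z for k in range(n_cov)
    ]
    f = np.column_stack(cols)  # (n, 4/2-wise features) -> n_fixed = 2*f-cols
    if scenario is Scenario.S1:
        g = f[:, :2]
    else:
        g = f
    return f, g


def _extract_arrays(params: ModelParams, trial_data):
    df = getattr(trial_data, "df", trial_data)
    if isinstance(df, pd.DataFrame) and len(df) == 0:
        return None
    z = df["z"].to_numpy(float)
    p = params.n_covariates
    if p == 1 and "x" in df.columns:
        x = df["x"].to_numpy(float).reshape(-1, 1)
    else:
        x = np.column_stack([df[f"x{k + 1}"].to_numpy(float) for k in range(p)])
    s = df["s"].to_numpy(float)
    t = df["t"].to_numpy(float) if "t" in df.columns else np.full(len(df), np.nan)
    return z, x, s, t


def build_design_matrices(params: ModelParams, trial_data) -> DesignMatrices:
    """Explicit stacked (M, W, R, y) after missing-T row deletion.

    Intended for small trials and for testing against the direct V-based
    conditioning formula; :func:`conditional_random_effects` never forms V.
    """
    arrs = _extract_arrays(params, trial_data)
    if arrs is None:
        raise ValueError("trial has no data rows")
    z, x, s, t = arrs
    f, g = _feature_rows(params.scenario, params.n_covariates, z, x)
    rows_M, rows_W, rows_y = [], [], []
    blocks = []
    sigma = params.sigma
    for j in range(z.shape[0]):
        Mj = np.kron(f[j], np.eye(2))  # rows: S then T
        Wj = np.kron(g[j], np.eye(2))
        if np.isnan(t[j]):
            rows_M.append(Mj[0])
            rows_W.append(Wj[0])
            rows_y.append(s[j])
            blocks.append(np.array([[sigma[0, 0]]]))
        else:
            rows_M.extend(Mj)
            rows_W.extend(Wj)
            rows_y.extend([s[j], t[j]])
            blocks.append(sigma)
    m = sum(b.shape[0] for b in blocks)
    R = np.zeros((m, m))
    pos = 0
    for b in blocks:
        k = b.shape[0]
        R[pos : pos + k, pos : pos + k] = b
        pos += k
    R[np.diag_indices_from(R)] += _R_FLOOR
    return DesignMatrices(
        M=np.array(rows_M), W=np.array(rows_W), R=R, y=np.array(rows_y)
    )


def conditional_random_effects(params: ModelParams, trial_data) -> ConditionalEffects:
    """Conditional law of the ongoing trial's random effects given its data.

    ``trial_data`` holds the trial's subject rows (columns z, x, s, t; NaN t
    = not yet observed).  With no data the prior (0, D) is returned.
    """
    arrs = _extract_arrays(params, trial_data)
    D = params.D
    q = D.shape[0]
    if arrs is None or arrs[0].shape[0] == 0:
        return ConditionalEffects(gamma_tilde=np.zeros(q), D_tilde=D.copy())
    z, x, s, t = arrs
    f, g = _feature_rows(params.scenario, params.n_covariates, z, x)

    mu_pairs = params.mu.reshape(-1, 2)  # (n_features, 2): (S, T) per feature
    fitted = f @ mu_pairs  # (n, 2)
    resid = np.column_stack([s, t]) - fitted

    sigma = params.sigma + _R_FLOOR * np.eye(2)
    try:
        sig_inv = np.linalg.inv(sigma)
    except np.linalg.LinAlgError as e:  # pragma: no cover - floored above
        raise np.linalg.LinAlgError(
            "residual covariance is singular; raise the residual-variance floor"
        ) from e
    miss = np.isnan(t)
    gc, gm = g[~miss], g[miss]
    rc, rm = resid[~miss], resid[miss][:, 0]

    # precision accumulation: W'R^{-1}W and W'R^{-1}(y - M mu)
    gdim = g.shape[1]
    prec = np.zeros((q, q))
    lin = np.zeros((gdim, 2))
    if gc.shape[0]:
        Gc = gc.T @ gc  # sum g g'
        prec += np.kron(Gc, sig_inv)
        lin += gc.T @ (rc @ sig_inv)
    if gm.shape[0]:
        inv_ss = 1.0 / sigma[0, 0]
        Gm = gm.T @ gm
        e11 = np.zeros((2, 2))
        e11[0, 0] = inv_ss
        prec += np.kron(Gm, e11)
        lin[:, 0] += gm.T @ rm * inv_ss
    b = lin.reshape(-1)  # row-major: pairs (S, T) per feature, matches kron

    D_inv = np.linalg.inv(D + 1e-12 * np.trace(D) / q * np.eye(q))
    A = D_inv + prec
    try:
        L = np.linalg.cholesky(A)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(
            "conditional precision is singular; raise the residual-variance floor"
        ) from e
    D_tilde = np.linalg.inv(A)
    D_tilde = 0.5 * (D_tilde + D_tilde.T)
    gamma_tilde = D_tilde @ b
    return ConditionalEffects(gamma_tilde=gamma_tilde, D_tilde=D_tilde)


def conditional_effect_joint(
    params: ModelParams, cond: ConditionalEffects, x
) -> TreatmentEffectJoint:
    """Joint law of (Delta_S(x), Delta_T(x)) for the ongoing trial."""
    xv = float(np.atleast_1d(x)[0])
    w_s, w_t = effect_weight_vectors(params.scenario, xv)
    x_arr = np.atleast_1d(np.asarray(x, float))
    mean = np.array(
        [
            params.beta_s + params.delta_s @ x_arr + w_s @ cond.gamma_tilde,
            params.beta_t + params.delta_t @ x_arr + w_t @ cond.gamma_tilde,
        ]
    )
    cov = np.array(
        [
            [w_s @ cond.D_tilde @ w_s, w_s @ cond.D_tilde @ w_t],
            [w_t @ cond.D_tilde @ w_s, w_t @ cond.D_tilde @ w_t],
        ]
    )
    return TreatmentEffectJoint(mean=mean, cov=cov, x=x_arr)


def psi_sp13_partial(params: ModelParams, cond: ConditionalEffects, x) -> float:
    """psi_SP13_N(x): sign-agreement probability for the ongoing trial."""
    return _psi13(conditional_effect_joint(params, cond, x))


def psi_sp123_partial(params: ModelParams, cond: ConditionalEffects, x) -> float:
    """psi_SP123_N(x): dangerous-paradox avoidance for the ongoing trial."""
    return _psi123(conditional_effect_joint(params, cond, x))
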