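"""Bivariate linear mixed model for meta-analytic surrogate evaluation.

The model links a surrogate endpoint S and a true endpoint T measured on
subject j of trial i, with treatment indicator Z and covariates X::

    S_ij = alpha_S + beta_S Z + sum_k gamma_Sk X_k + sum_k delta_Sk X_k Z
           + a_Si + b_Si Z [+ c_Si X + d_Si X Z] + eps_Sij
    T_ij = (same structure with T subscripts)

Subject-level errors (eps_S, eps_T) are bivariate normal with covariance
``sigma``; trial-level random effects are multivariate normal with
covariance ``D``.  Two scenarios are supported:

* **S1** — covariate effects are fixed across trials: random effects are
  (a_S, a_T, b_S, b_T), D is 4x4.
* **S2** — a single covariate whose main effect and treatment interaction
  vary by trial: random effects are (a_S, a_T, b_S, b_T, c_S, c_T, d_S, d_T),
  D is 8x8.

The trial-level treatment effects at covariate level x,

    Delta_S(x) = beta_S + delta_S x + b_S (+ x d_S under S2)
    Delta_T(x) = beta_T + delta_T x + b_T (+ x d_T under S2)

are jointly bivariate normal across trials; :func:`joint_effect_distribution`
returns their law, which is the basis of every paradox-risk measure.

Naming of D entries follows the field's flat notation, in which each random
effect carries a single label:

    ========  =======  =====
    effect    label    index
    ========  =======  =====
    a_S       s        0
    a_T       t        1
    b_S       a        2
    b_T       b        3
    c_S       cs       4
    c_T       ct       5
    d_S       ds       6
    d_T       dt       7
    ========  =======  =====

so e.g. ``d_ab = Cov(b_S, b_T) = D[2, 3]`` and ``d_a_ds = Cov(b_S, d_S)
= D[2, 6]``.  Flat parameter keys join two labels: ``d_ss``, ``d_ab`` for
single-character labels, ``d_a_ds``, ``d_ds_dt`` otherwise.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Scenario",
    "ModelParams",
    "TreatmentEffectJoint",
    "joint_effect_distribution",
    "rtrial2",
    "RE_LABELS",
    "re_entry_name",
]

_PSD_TOL = 1e-8

#: flat-notation label of each random effect, in storage order
RE_LABELS = ("s", "t", "a", "b", "cs", "ct", "ds", "dt")


class Scenario(str, enum.Enum):
    """S1: covariate effects fixed across trials; S2: trial-varying."""

    S1 = "S1"
    S2 = "S2"

    @property
    def n_random_effects(self) -> int:
        return 4 if self is Scenario.S1 else 8


def re_entry_name(i: int, j: int) -> str:
    """Flat key for entry (i, j) of D, e.g. (2, 3) -> 'd_ab'."""
    li, lj = RE_LABELS[min(i, j)], RE_LABELS[max(i, j)]
    if len(li) == 1 and len(lj) == 1:
        return f"d_{li}{lj}"
    return f"d_{li}_{lj}"


def _re_name_to_index() -> dict[str, tuple[int, int]]:
    out: dict[str, tuple[int, int]] = {}
    for i in range(8):
        for j in range(i, 8):
            out[re_entry_name(i, j)] = (i, j)
            # tolerate the fully-underscored spelling, e.g. d_a_b
            out[f"d_{RE_LABELS[i]}_{RE_LABELS[j]}"] = (i, j)
    return out


_RE_NAME_TO_INDEX = _re_name_to_index()


def _check_psd(mat: np.ndarray, name: str, tol: float = _PSD_TOL) -> None:
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    w = np.linalg.eigvalsh(mat)
    if w.min() < -tol * max(1.0, abs(w.max())):
        raise ValueError(
            f"{name} is not positive semidefinite (min eigenvalue {w.min():.3g})"
        )


@dataclass(frozen=True)
class ModelParams:
    """Complete parameter set of the bivariate mixed model.

    Parameters
    ----------
    scenario
        :class:`Scenario` member (or the strings "S1"/"S2").
    alpha_s, alpha_t
        Endpoint intercepts.
    beta_s, beta_t
        Treatment main effects.
    gamma_s, gamma_t
        Covariate main effects, length-p arrays (p >= 0).
    delta_s, delta_t
        Covariate-by-treatment interactions, length-p arrays.
    D
        Random-effect covariance, 4x4 (S1) or 8x8 (S2), ordered
        (a_S, a_T, b_S, b_T[, c_S, c_T, d_S, d_T]).
    sigma
        2x2 residual covariance of (eps_S, eps_T).
    """

    scenario: Scenario
    alpha_s: float
    alpha_t: float
    beta_s: float
    beta_t: float
    gamma_s: np.ndarray
    gamma_t: np.ndarray
    delta_s: np.ndarray
    delta_t: np.ndarray
    D: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "scenario", Scenario(self.scenario))
        for name in ("gamma_s", "gamma_t", "delta_s", "delta_t"):
            object.__setattr__(
                self, name, np.atleast_1d(np.asarray(getattr(self, name), float))
            )
        object.__setattr__(self, "D", np.asarray(self.D, float))
        object.__setattr__(self, "sigma", np.asarray(self.sigma, float))

        p = self.gamma_s.shape[0]
        if any(v.shape != (p,) for v in (self.gamma_t, self.delta_s, self.delta_t)):
            raise ValueError("gamma_s, gamma_t, delta_s, delta_t must share length")
        if self.scenario is Scenario.S2 and p != 1:
            raise ValueError(
                "Scenario S2 is derived for a single scalar/binary covariate; "
                f"got {p} covariates"
            )
        q = self.scenario.n_random_effects
        if self.D.shape != (q, q):
            raise ValueError(f"D must be {q}x{q} under {self.scenario.value}")
        if self.sigma.shape != (2, 2):
            raise ValueError("sigma must be 2x2")
        _check_psd(self.D, "D")
        _check_psd(self.sigma, "sigma")
        if np.any(np.diag(self.D) < 0) or np.any(np.diag(self.sigma) < 0):
            raise ValueError("variance diagonals must be nonnegative")

    # -- convenience -------------------------------------------------------

    @property
    def n_covariates(self) -> int:
        return self.gamma_s.shape[0]

    @property
    def n_fixed(self) -> int:
        return 4 + 4 * self.n_covariates

    @property
    def mu(self) -> np.ndarray:
        """Fixed effects as one vector.

        Ordered (alpha_S, alpha_T, beta_S, beta_T, gamma_S1, gamma_T1, ...,
        delta_S1, delta_T1, ...), i.e. endpoint pairs per design feature
        (1, Z, X_k, X_k Z).
        """
        parts = [self.alpha_s, self.alpha_t, self.beta_s, self.beta_t]
        for k in range(self.n_covariates):
            parts += [self.gamma_s[k], self.gamma_t[k]]
        for k in range(self.n_covariates):
            parts += [self.delta_s[k], self.delta_t[k]]
        return np.array(parts, float)

    def d(self, label_i: str, label_j: str) -> float:
        """Named D entry, e.g. ``params.d('a', 'b')`` for Cov(b_S, b_T)."""
        i, j = RE_LABELS.index(label_i), RE_LABELS.index(label_j)
        return float(self.D[i, j])

    # -- flat serialization ------------------------------------------------

    def to_dict(self) -> dict:
        """Flat key/value form (round-trips through :meth:`from_dict`)."""
        out: dict = {
            "scenario": self.scenario.value,
            "n_covariates": self.n_covariates,
            "alpha_S": self.alpha_s,
            "alpha_T": self.alpha_t,
            "beta_S": self.beta_s,
            "beta_T": self.beta_t,
        }
        for k in range(self.n_covariates):
            suf = "" if self.n_covariates == 1 else f"_{k + 1}"
            out[f"gamma_S{suf}"] = float(self.gamma_s[k])
            out[f"gamma_T{suf}"] = float(self.gamma_t[k])
            out[f"delta_S{suf}"] = float(self.delta_s[k])
            out[f"delta_T{suf}"] = float(self.delta_t[k])
        q = self.scenario.n_random_effects
        for i in range(q):
            for j in range(i, q):
                out[re_entry_name(i, j)] = float(self.D[i, j])
        out["sigma_ss"] = float(self.sigma[0, 0])
        out["sigma_st"] = float(self.sigma[0, 1])
        out["sigma_tt"] = float(self.sigma[1, 1])
        return out

    @classmethod
    def from_dict(cls, cfg: dict) -> "ModelParams":
        scenario = Scenario(cfg["scenario"])
        p = int(cfg.get("n_covariates", 1))
        q = scenario.n_random_effects

        def cov_vec(base: str) -> np.ndarray:
            if p == 1 and base in cfg:
                return np.array([float(cfg[base])])
            return np.array([float(cfg[f"{base}_{k + 1}"]) for k in range(p)])

        D = np.zeros((q, q))
        for i in range(q):
            for j in range(i, q):
                key = re_entry_name(i, j)
                alt = f"d_{RE_LABELS[i]}_{RE_LABELS[j]}"
                if key in cfg:
                    D[i, j] = D[j, i] = float(cfg[key])
                elif alt in cfg:
                    D[i, j] = D[j, i] = float(cfg[alt])
                else:
                    raise KeyError(f"missing D entry {key}")
        sigma = np.array(
            [
                [float(cfg["sigma_ss"]), float(cfg["sigma_st"])],
                [float(cfg["sigma_st"]), float(cfg["sigma_tt"])],
            ]
        )
        return cls(
            scenario=scenario,
            alpha_s=float(cfg["alpha_S"]),
            alpha_t=float(cfg["alpha_T"]),
            beta_s=float(cfg["beta_S"]),
            beta_t=float(cfg["beta_T"]),
            gamma_s=cov_vec("gamma_S"),
            gamma_t=cov_vec("gamma_T"),
            delta_s=cov_vec("delta_S"),
            delta_t=cov_vec("delta_T"),
            D=D,
            sigma=sigma,
        )


@dataclass(frozen=True)
class TreatmentEffectJoint:
    """Bivariate-normal law of (Delta_S(x), Delta_T(x)) across trials."""

    mean: np.ndarray  # (E Delta_S(x), E Delta_T(x))
    cov: np.ndarray  # [[daa*, dab*], [dab*, dbb*]]
    x: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", np.asarray(self.mean, float).reshape(2))
        object.__setattr__(self, "cov", np.asarray(self.cov, float).reshape(2, 2))
        object.__setattr__(self, "x", np.atleast_1d(np.asarray(self.x, float)))


def effect_weight_vectors(scenario: Scenario, x: float) -> tuple[np.ndarray, np.ndarray]:
    """Random-effect loadings of (Delta_S(x), Delta_T(x)).

    Delta_S(x) loads b_S with weight 1 (and d_S with weight x under S2);
    Delta_T(x) likewise on b_T (and d_T).
    """
    q = scenario.n_random_effects
    w_s = np.zeros(q)
    w_t = np.zeros(q)
    w_s[2] = 1.0
    w_t[3] = 1.0
    if scenario is Scenario.S2:
        w_s[6] = x
        w_t[7] = x
    return w_s, w_t


def joint_effect_distribution(params: ModelParams, x) -> TreatmentEffectJoint:
    """Joint law of the trial-level treatment effects at covariate profile x.

    Under S1 the covariate only shifts the mean:
    mean = (beta_S + delta_S . x, beta_T + delta_T . x), cov = (daa, dab, dbb).
    Under S2 (scalar x) the covariance also changes::

        daa* = daa + x^2 d_ds_ds + 2 x d_a_ds
        dab* = dab + x d_a_dt + x d_b_ds + x^2 d_ds_dt
        dbb* = dbb + x^2 d_dt_dt + 2 x d_b_dt

    Raises
    ------
    ValueError
        If x has the wrong length, or the resulting covariance is not PSD
        (an invalid parameter set; it is rejected, never clipped).
    """
    x = np.atleast_1d(np.asarray(x, float))
    if x.shape != (params.n_covariates,):
        raise ValueError(
            f"x must have length {params.n_covariates}, got {x.shape[0]}"
        )
    mean = np.array(
        [
            params.beta_s + params.delta_s @ x,
            params.beta_t + params.delta_t @ x,
        ]
    )
    if params.scenario is Scenario.S1:
        cov = params.D[2:4, 2:4].copy()
    else:
        w_s, w_t = effect_weight_vectors(params.scenario, float(x[0]))
        cov = np.array(
            [
                [w_s @ params.D @ w_s, w_s @ params.D @ w_t],
                [w_t @ params.D @ w_s, w_t @ params.D @ w_t],
            ]
        )
    cov = 0.5 * (cov + cov.T)
    if cov[0, 0] < 0 or cov[1, 1] < 0 or np.linalg.det(cov) < -_PSD_TOL:
        raise ValueError(
            "joint treatment-effect covariance is not PSD at "
            f"x={x.tolist()}: {cov.tolist()}"
        )
    return TreatmentEffectJoint(mean=mean, cov=cov, x=x)


def rtrial2(D) -> float:
    """Trial-level surrogacy measure R^2_trial.

    Proportion of the between-trial variance of the treatment effect on the
    true endpoint explained by the surrogate-related random effects
    (a_S, b_S):

        R^2 = (d_sb, d_ab) [[d_ss, d_sa], [d_sa, d_aa]]^{-1} (d_sb, d_ab)' / d_bb

    Accepts a :class:`ModelParams` or a D matrix (only the base 4x4 block is
    used).
    """
    if isinstance(D, ModelParams):
        D = D.D
    D = np.asarray(D, float)
    block = np.array([[D[0, 0], D[0, 2]], [D[0, 2], D[2, 2]]])
    v = np.array([D[0, 3], D[2, 3]])
    dbb = D[3, 3]
    det = np.linalg.det(block)
    if abs(det) < 1e-12 * max(1.0, abs(block).max() ** 2):
        raise np.linalg.LinAlgError(
            "the (a_S, b_S) covariance block [[d_ss, d_sa], [d_sa, d_aa]] is singular"
        )
    if dbb <= 0:
        raise ValueError("d_bb must be positive")
    return float(v @ np.linalg.solve(block, v) / dbb)
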