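"""Synthetic meta-analytic data and the bias/coverage replication study.

The generator emulates the simulation design used to validate the
covariate-adjusted paradox measures: N trials (30 or 100) of n subjects
each (20, 50 or 500), half of each trial randomised to treatment, a binary
covariate balanced across the treatment-by-covariate cells, trial-level
random effects drawn from the 4- (S1) or 8-dimensional (S2) normal, and
subject-level errors from a bivariate normal — or, for sensitivity
analyses, a t with 15 degrees of freedom or a skew-normal, both centred at
zero and covariance-matched to sigma.

Default generating parameters:

    alpha_S = alpha_T = 1, beta_S = 2, beta_T = 1,
    gamma_S = gamma_T = 0, delta_S = -1, delta_T = 1;
    d_ss = d_tt = d_aa = d_bb = 1, d_ab = 0.5, remaining base
    off-diagonals 0.3; under S2 additionally d_cs_cs = d_ct_ct =
    d_ds_ds = d_dt_dt = 1 with every off-diagonal involving the new
    covariate random effects equal to 0.3.

The residual covariance is not part of the published design; the default
here is sigma_ss = sigma_tt = 1, sigma_st = 0.3 (the psi truths do not
depend on sigma).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import skewnorm

from .data_io import MetaDataset
from .gibbs import PriorSpec, draws_to_params, gibbs_fit, posterior_measures
from .measures import psi_sp13, psi_sp123, s_threshold_closed_form
from .model import ModelParams, Scenario, joint_effect_distribution
from .partial_trial import (
    conditional_random_effects,
    psi_sp123_partial,
    psi_sp13_partial,
)

logger = logging.getLogger("sprisk")

__all__ = [
    "default_parameters",
    "SimulationDesign",
    "simulate_meta",
    "simulate_trial_effects",
    "run_study",
]

ERROR_FAMILIES = ("normal", "t15", "skew_normal")


def default_parameters(scenario, sigma_st: float = 0.3) -> ModelParams:
    """The simulation-study generating parameter set for S1 or S2."""
    scenario = Scenario(scenario)
    base = np.full((4, 4), 0.3)
    np.fill_diagonal(base, 1.0)
    base[2, 3] = base[3, 2] = 0.5  # d_ab
    if scenario is Scenario.S1:
        D = base
    else:
        D = np.full((8, 8), 0.3)
        D[:4, :4] = base
        np.fill_diagonal(D, 1.0)
    return ModelParams(
        scenario=scenario,
        alpha_s=1.0,
        alpha_t=1.0,
        beta_s=2.0,
        beta_t=1.0,
        gamma_s=[0.0],
        gamma_t=[0.0],
        delta_s=[-1.0],
        delta_t=[1.0],
        D=D,
        sigma=np.array([[1.0, sigma_st], [sigma_st, 1.0]]),
    )


@dataclass(frozen=True)
class SimulationDesign:
    """Design of one simulated meta-analysis (and of the replication study)."""

    scenario: Scenario = Scenario.S1
    n_trials: int = 30
    n_per_trial: int = 50
    n_replicates: int = 200
    error_family: str = "normal"
    params: Optional[ModelParams] = None
    seed: Optional[int] = None

    def __post_init__(self):
        object.__setattr__(self, "scenario", Scenario(self.scenario))
        if self.error_family not in ERROR_FAMILIES:
            raise ValueError(f"error_family must be one of {ERROR_FAMILIES}")
        if self.params is None:
            object.__setattr__(self, "params", default_parameters(self.scenario))
        elif self.params.scenario is not self.scenario:
            raise ValueError("params.scenario does not match design.scenario")
        # validated on construction so bad user edits fail before any draw
        if np.linalg.eigvalsh(self.params.D).min() <= 0:
            raise ValueError("generating D must be positive definite")


def _skewnorm_std_params(shape_ratio: float = 0.1) -> tuple[float, float, float]:
    """(shape, loc, scale) of a skew-normal with mean 0, variance 1.

    The shape parameter is tied to the scale as a = shape_ratio * omega and
    omega solved so the variance is 1; the location centres the mean at 0.
    """

    def var_minus_1(omega):
        a = shape_ratio * omega
        delta = a / np.sqrt(1 + a * a)
        return omega**2 * (1 - 2 * delta**2 / np.pi) - 1.0

    omega = brentq(var_minus_1, 0.5, 5.0)
    a = shape_ratio * omega
    delta = a / np.sqrt(1 + a * a)
    loc = -omega * delta * np.sqrt(2 / np.pi)
    return a, loc, omega


def _draw_errors(rng, n: int, sigma: np.ndarray, family: str) -> np.ndarray:
    """n draws of (eps_S, eps_T), mean 0, covariance sigma, chosen family."""
    L = np.linalg.cholesky(sigma)
    if family == "normal":
        return rng.standard_normal((n, 2)) @ L.T
    if family == "t15":
        # multivariate t_15 scaled so the covariance equals sigma
        nu = 15.0
        z = rng.standard_normal((n, 2)) @ np.linalg.cholesky(sigma * (nu - 2) / nu).T
        w = np.sqrt(nu / rng.chisquare(nu, size=n))
        return z * w[:, None]
    if family == "skew_normal":
        a, loc, omega = _skewnorm_std_params()
        u = skewnorm.rvs(a, loc=loc, scale=omega, size=(n, 2), random_state=rng)
        return u @ L.T
    raise ValueError(family)


def _balanced_assignment(rng, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Treatment and binary covariate, balanced within trial.

    When n is divisible by 4 the four (z, x) cells are exactly equal;
    otherwise z is split as evenly as possible and x is Bernoulli(0.5).
    """
    if n % 4 == 0:
        cells = np.repeat(np.arange(4), n // 4)
        rng.shuffle(cells)
        z = (cells >= 2).astype(float)
        x = (cells % 2).astype(float)
    else:
        z = np.zeros(n)
        z[rng.permutation(n)[: n // 2]] = 1.0
        z = 1.0 - z  # ceil(n/2) treated
        x = (rng.random(n) < 0.5).astype(float)
    return z, x


def simulate_trial_effects(params: ModelParams, n_trials: int, x: float, rng):
    """Exact per-trial (Delta_S(x), Delta_T(x)) draws — no subject noise."""
    gam = rng.multivariate_normal(np.zeros(params.D.shape[0]), params.D, size=n_trials)
    d_s = gam[:, 2].copy()
    d_t = gam[:, 3].copy()
    if params.scenario is Scenario.S2:
        d_s += x * gam[:, 6]
        d_t += x * gam[:, 7]
    d_s += params.beta_s + params.delta_s[0] * x
    d_t += params.beta_t + params.delta_t[0] * x
    return np.column_stack([d_s, d_t])


def simulate_meta(design: SimulationDesign, rng=None) -> MetaDataset:
    """Generate one long-format meta-analytic dataset under the design."""
    if rng is None:
        rng = np.random.default_rng(design.seed)
    p = design.params
    q = p.D.shape[0]
    rows = []
    for i in range(design.n_trials):
        n = design.n_per_trial
        gam = rng.multivariate_normal(np.zeros(q), p.D)
        z, x = _balanced_assignment(rng, n)
        eps = _draw_errors(rng, n, p.sigma, design.error_family)
        s = (
            p.alpha_s + p.beta_s * z + p.gamma_s[0] * x + p.delta_s[0] * x * z
            + gam[0] + gam[2] * z
        )
        t = (
            p.alpha_t + p.beta_t * z + p.gamma_t[0] * x + p.delta_t[0] * x * z
            + gam[1] + gam[3] * z
        )
        if p.scenario is Scenario.S2:
            s = s + gam[4] * x + gam[6] * x * z
            t = t + gam[5] * x + gam[7] * x * z
        s = s + eps[:, 0]
        t = t + eps[:, 1]
        rows.append(
            pd.DataFrame(
                {
                    "trial": i + 1,
                    "subject": np.arange(1, n + 1),
                    "z": z.astype(int),
                    "x": x,
                    "s": s,
                    "t": t,
                }
            )
        )
    return MetaDataset(pd.concat(rows, ignore_index=True), x_cols=("x",))


def _true_values(params: ModelParams, x_levels, alpha, arm_counts) -> dict:
    truth = {}
    for x in x_levels:
        joint = joint_effect_distribution(params, [x])
        truth[("psi_sp13", x)] = psi_sp13(joint)
        truth[("psi_sp123", x)] = psi_sp123(joint)
        if arm_counts is not None:
            truth[("s", x)] = s_threshold_closed_form(
                params, [x], alpha, arm_counts[0], arm_counts[1]
            )
    return truth


def run_study(
    design: SimulationDesign,
    x_levels=(0.0, 1.0),
    alpha: float = 0.05,
    arm_counts: Optional[tuple] = None,
    include_partial: bool = False,
    estimator: str = "gibbs",
    iterations: int = 2000,
    burn_in: int = 500,
    thinning: int = 1,
    prior: Optional[PriorSpec] = None,
    level: float = 0.95,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Replicate the estimation pipeline and tabulate bias, SE and coverage.

    For each of ``design.n_replicates`` replicates a dataset is simulated,
    the model fit (Gibbs), and the posterior measures computed at each x
    level; truth is analytic from the generating parameters.  With
    ``include_partial=True`` the final trial is treated as ongoing with
    half the subjects of the others: the model is fit on the other trials
    and psi_SP13_N / psi_SP123_N computed per draw from its partial data.
    ``estimator='oracle'`` substitutes the truth for every estimate (a
    self-check: zero bias, full coverage).

    Returns a table with one row per (quantity, x): truth, mean estimate,
    bias, empirical SE, and coverage of the ``level`` credible intervals.
    Replicate-level estimation failures are recorded and excluded, with the
    count reported in ``n_failed``.
    """
    if design.n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    if estimator not in ("gibbs", "oracle"):
        raise ValueError("estimator must be 'gibbs' or 'oracle'")
    seed_seq = np.random.SeedSequence(design.seed if seed is None else seed)
    truth = _true_values(design.params, x_levels, alpha, arm_counts)
    if include_partial:
        for x in x_levels:
            # the unconditional value is the reference for the partial measure
            truth[("psi_sp13N", x)] = truth[("psi_sp13", x)]
            truth[("psi_sp123N", x)] = truth[("psi_sp123", x)]

    records: dict = {key: [] for key in truth}
    n_failed = 0
    for rep, child in enumerate(seed_seq.spawn(design.n_replicates)):
        rng = np.random.default_rng(child)
        rep_design = replace(design, seed=None)
        if include_partial:
            half = replace(rep_design, n_trials=1,
                           n_per_trial=max(4, design.n_per_trial // 2))
            hist = simulate_meta(replace(rep_design, n_trials=design.n_trials - 1),
                                 rng=rng)
            ongoing = simulate_meta(half, rng=rng)
            data = hist
        else:
            data = simulate_meta(rep_design, rng=rng)
        if estimator == "oracle":
            for key, val in truth.items():
                records[key].append((val, val, val))
            continue
        try:
            fit_seed = int(np.random.default_rng(child).integers(2**31 - 1))
            draws = gibbs_fit(
                data, design.scenario, prior=prior, iterations=iterations,
                burn_in=burn_in, thinning=thinning, seed=fit_seed,
            )
            table = posterior_measures(
                draws, x_levels=x_levels, alpha=alpha, level=level,
                arm_counts=arm_counts,
            )
            for _, row in table.iterrows():
                key = (row["quantity"], row["x"])
                if key in records:
                    records[key].append((row["mean"], row["lower"], row["upper"]))
            if include_partial:
                lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
                trial_df = ongoing.df.assign(t=np.nan)  # surrogate-only data
                for x in x_levels:
                    vals13 = np.empty(draws.n_draws)
                    vals123 = np.empty(draws.n_draws)
                    for i in range(draws.n_draws):
                        par = draws_to_params(draws, i)
                        cond = conditional_random_effects(par, trial_df)
                        vals13[i] = psi_sp13_partial(par, cond, x)
                        vals123[i] = psi_sp123_partial(par, cond, x)
                    for nm, v in (("psi_sp13N", vals13), ("psi_sp123N", vals123)):
                        records[(nm, x)].append(
                            (v.mean(), np.quantile(v, lo_q), np.quantile(v, hi_q))
                        )
        except (np.linalg.LinAlgError, FloatingPointError, ValueError) as err:
            n_failed += 1
            logger.warning("replicate %d failed and was excluded: %s", rep, err)

    rows = []
    for (quantity, x), vals in records.items():
        if not vals:
            continue
        arr = np.array(vals)  # (reps, 3): mean, lower, upper
        tv = truth[(quantity, x)]
        rows.append(
            {
                "quantity": quantity,
                "x": x,
                "true_value": tv,
                "mean_estimate": arr[:, 0].mean(),
                "bias": arr[:, 0].mean() - tv,
                "empirical_se": arr[:, 0].std(ddof=1),
                "coverage": float(np.mean((arr[:, 1] <= tv) & (tv <= arr[:, 2]))),
                "n_replicates": arr.shape[0],
                "n_failed": n_failed,
            }
        )
    return pd.DataFrame(rows)
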