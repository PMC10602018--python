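"""Conjugate Gibbs sampling for the bivariate mixed model.

Priors: mu ~ N(0, Sigma0) with diffuse Sigma0 = 1e6 I by default, and
Wishart priors on the precision matrices, sigma^{-1} ~ W(v_sigma, G),
D^{-1} ~ W(v_D, F), in the convention E[W(v, S)] = v S (scipy's).  The
defaults follow the simulation prior W(q + 1, I_q / (q + 2)) where q is the
dimension of the associated random vector.

All four full conditionals are conjugate:

    D^{-1} | .      ~ W(N + v_D, (sum_i gamma_i gamma_i' + F^{-1})^{-1})
    sigma^{-1} | .  ~ W(sum_i n_i + v_sigma, (S_res + G^{-1})^{-1})
    gamma_i | .     ~ N(S2 sum_j W_ij' sigma^{-1}(Y_ij - M_ij mu), S2)
    mu | .          ~ N(S3 sum_ij M_ij' sigma^{-1}(Y_ij - W_ij gamma_i), S3)

with S_res the residual cross-product sum, S2 = (sum_j W' sigma^{-1} W +
D^{-1})^{-1} and S3 = (sum_ij M' sigma^{-1} M + Sigma0^{-1})^{-1}.  The
sweep order is D -> sigma -> {gamma_i} -> mu (any fixed order gives a valid
Gibbs kernel).

The per-subject designs factor as M_ij = f_ij' (x) I_2 with feature vector
f = (1, Z, X_k..., X_k Z...) and W_ij = g' (x) I_2 with g = (1, Z) under S1
or g = f under S2, so every conditional reduces to Kronecker algebra on
small per-trial cross-product sums; a sweep costs O(n + N q^3).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp, ndtri
from scipy.stats import wishart

from .data_io import MetaDataset
from .measures import psi_values
from .model import ModelParams, Scenario

logger = logging.getLogger("sprisk")

__all__ = [
    "PriorSpec",
    "PosteriorDraws",
    "gibbs_fit",
    "posterior_measures",
    "marginal_waic",
    "WaicResult",
    "gelman_rubin",
    "draws_to_params",
    "write_draws",
    "read_draws",
]


@dataclass(frozen=True)
class PriorSpec:
    """Prior hyperparameters for (mu, sigma, D)."""

    Sigma0: np.ndarray
    v_sigma: float
    G: np.ndarray
    v_D: float
    F: np.ndarray

    def __post_init__(self):
        if self.v_sigma < 2:
            raise ValueError("v_sigma must be >= 2")
        if self.v_D < self.F.shape[0]:
            raise ValueError("v_D must be >= dim(D)")
        for name in ("Sigma0", "G", "F"):
            m = getattr(self, name)
            if np.linalg.eigvalsh(m).min() <= 0:
                raise ValueError(f"{name} must be positive definite")

    @classmethod
    def default(cls, n_fixed: int, q: int) -> "PriorSpec":
        """Diffuse N(0, 1e6 I) on mu; W(q+1, I/(q+2)) on each precision."""
        return cls(
            Sigma0=1e6 * np.eye(n_fixed),
            v_sigma=3.0,
            G=np.eye(2) / 4.0,
            v_D=float(q + 1),
            F=np.eye(q) / (q + 2.0),
        )


@dataclass
class PosteriorDraws:
    """Retained Gibbs draws plus chain metadata."""

    scenario: Scenario
    n_covariates: int
    mu: np.ndarray  # (n_draws, n_fixed)
    D: np.ndarray  # (n_draws, q, q)
    sigma: np.ndarray  # (n_draws, 2, 2)
    chain_id: np.ndarray  # (n_draws,)
    gamma: Optional[np.ndarray] = None  # (n_draws, N, q)
    meta: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.mu.shape[0]


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------


def _prepare(data, n_covariates: int, scenario: Scenario):
    """Sort by trial, drop unusable trials, build feature arrays."""
    df = getattr(data, "df", data)
    if df["t"].isna().any():
        ds = data if isinstance(data, MetaDataset) else MetaDataset(df, x_cols=("x",))
        df = ds.complete_case().df
    arms = df.groupby("trial")["z"].agg(["min", "max"])
    single = arms[arms["min"] == arms["max"]].index.tolist()
    if single:
        logger.warning(
            "dropping %d trial(s) with a single treatment arm: %s", len(single), single
        )
        df = df[~df["trial"].isin(single)]
    if df.empty:
        raise ValueError("no usable trials (need both arms and observed S, T)")
    df = df.sort_values(["trial"], kind="stable").reset_index(drop=True)
    trials, idx = np.unique(df["trial"].to_numpy(), return_inverse=True)
    order = np.argsort(idx, kind="stable")
    df = df.iloc[order].reset_index(drop=True)
    idx = idx[order]
    starts = np.searchsorted(idx, np.arange(len(trials)))

    z = df["z"].to_numpy(float)
    if n_covariates == 1 and "x" in df.columns:
        x = df["x"].to_numpy(float).reshape(-1, 1)
    else:
        x = np.column_stack(
            [df[f"x{k + 1}"].to_numpy(float) for k in range(n_covariates)]
        )
    y = df[["s", "t"]].to_numpy(float)
    cols = [np.ones(len(df)), z] + [x[:, k] for k in range(n_covariates)] + [
        x[:, k] * z for k in range(n_covariates)
    ]
    F = np.column_stack(cols)
    G = F[:, :2] if scenario is Scenario.S1 else F
    N = len(trials)
    # per-trial sum g g' (constant across sweeps)
    GG = np.stack(
        [
            G[starts[i] : (starts[i + 1] if i + 1 < N else len(df))].T
            @ G[starts[i] : (starts[i + 1] if i + 1 < N else len(df))]
            for i in range(N)
        ]
    )
    return {
        "trials": trials,
        "trial_idx": idx,
        "starts": starts,
        "y": y,
        "F": F,
        "G": G,
        "GG": GG,
        "FF": F.T @ F,
        "N": N,
        "n": len(df),
    }


def _safe_wishart_scale(mat: np.ndarray) -> np.ndarray:
    """Symmetrise; clip tiny negative eigenvalues from numerical jitter."""
    mat = 0.5 * (mat + mat.T)
    w = np.linalg.eigvalsh(mat)
    if w.min() <= 0:
        logger.warning(
            "non-PD Wishart scale (min eigenvalue %.3g); clipping at 1e-10", w.min()
        )
        vals, vecs = np.linalg.eigh(mat)
        mat = (vecs * np.maximum(vals, 1e-10)) @ vecs.T
    return mat


def _segment_sum(arr: np.ndarray, starts: np.ndarray) -> np.ndarray:
    return np.add.reduceat(arr, starts, axis=0)


def _batch_kron_2(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """kron(A_i, B) for stacked A (N, k, k) and fixed 2x2 B -> (N, 2k, 2k)."""
    N, k, _ = A.shape
    out = A[:, :, None, :, None] * B[None, None, :, None, :]
    return out.reshape(N, 2 * k, 2 * k)


def _run_chain(prep, prior: PriorSpec, iterations, burn_in, thinning, rng,
               store_random_effects, chain_id):
    y, F, G, GG, FF = prep["y"], prep["F"], prep["G"], prep["GG"], prep["FF"]
    starts, idx, N, n = prep["starts"], prep["trial_idx"], prep["N"], prep["n"]
    nfeat = F.shape[1]
    gfeat = G.shape[1]
    q = 2 * gfeat
    pdim = 2 * nfeat

    Sigma0_inv = np.linalg.inv(prior.Sigma0)
    G_prior_inv = np.linalg.inv(prior.G)
    F_prior_inv = np.linalg.inv(prior.F)

    # init: pooled least squares for mu; identity variances; gamma = 0
    Amu = np.column_stack(
        [np.linalg.lstsq(F, y[:, 0], rcond=None)[0],
         np.linalg.lstsq(F, y[:, 1], rcond=None)[0]]
    )  # (nfeat, 2)
    D_inv = np.eye(q)
    sig_inv = np.eye(2)
    gam = np.zeros((N, q))

    n_keep = (iterations - burn_in) // thinning
    out_mu = np.empty((n_keep, pdim))
    out_D = np.empty((n_keep, q, q))
    out_sig = np.empty((n_keep, 2, 2))
    out_gam = np.empty((n_keep, N, q)) if store_random_effects else None

    keep = 0
    for it in range(iterations):
        # --- D^{-1} | .
        scale = _safe_wishart_scale(np.linalg.inv(gam.T @ gam + F_prior_inv))
        D_inv = wishart.rvs(df=N + prior.v_D, scale=scale, random_state=rng)
        D_inv = 0.5 * (D_inv + D_inv.T)

        # --- sigma^{-1} | .
        gam_pairs = gam.reshape(N, gfeat, 2)
        rand_part = np.einsum("nk,nkd->nd", G, gam_pairs[idx])
        e = y - F @ Amu - rand_part
        scale = _safe_wishart_scale(np.linalg.inv(e.T @ e + G_prior_inv))
        sig_inv = wishart.rvs(df=n + prior.v_sigma, scale=scale, random_state=rng)
        sig_inv = 0.5 * (sig_inv + sig_inv.T)

        # --- gamma_i | .
        e0 = y - F @ Amu
        u = e0 @ sig_inv
        B = _segment_sum(G[:, :, None] * u[:, None, :], starts)  # (N, gfeat, 2)
        b = B.reshape(N, q)
        prec = _batch_kron_2(GG, sig_inv) + D_inv[None]
        L = np.linalg.cholesky(prec)
        mean = np.linalg.solve(prec, b[:, :, None])
        noise = np.linalg.solve(
            np.transpose(L, (0, 2, 1)), rng.standard_normal((N, q, 1))
        )
        gam = (mean + noise)[:, :, 0]

        # --- mu | .
        gam_pairs = gam.reshape(N, gfeat, 2)
        rand_part = np.einsum("nk,nkd->nd", G, gam_pairs[idx])
        r = y - rand_part
        b_mu = (F.T @ (r @ sig_inv)).reshape(pdim)
        prec_mu = np.kron(FF, sig_inv) + Sigma0_inv
        L_mu = np.linalg.cholesky(prec_mu)
        mean_mu = np.linalg.solve(prec_mu, b_mu)
        mu = mean_mu + np.linalg.solve(L_mu.T, rng.standard_normal(pdim))
        Amu = mu.reshape(nfeat, 2)

        if not (np.isfinite(mu).all() and np.isfinite(D_inv).all()
                and np.isfinite(sig_inv).all()):
            raise FloatingPointError(
                f"divergent chain: non-finite draw at iteration {it}"
            )

        if it >= burn_in and (it - burn_in) % thinning == 0:
            out_mu[keep] = mu
            D_draw = np.linalg.inv(D_inv)
            sig_draw = np.linalg.inv(sig_inv)
            # exact symmetry: covariance draws are defined by one triangle
            out_D[keep] = np.triu(D_draw) + np.triu(D_draw, 1).T
            out_sig[keep] = np.triu(sig_draw) + np.triu(sig_draw, 1).T
            if store_random_effects:
                out_gam[keep] = gam
            keep += 1

    return out_mu[:keep], out_D[:keep], out_sig[:keep], (
        out_gam[:keep] if store_random_effects else None
    )


def gibbs_fit(
    data,
    scenario,
    prior: Optional[PriorSpec] = None,
    iterations: int = 4000,
    burn_in: int = 1000,
    thinning: int = 1,
    chains: int = 1,
    seed: Optional[int] = None,
    store_random_effects: bool = False,
) -> PosteriorDraws:
    """Fit the bivariate mixed model by Gibbs sampling.

    ``data`` is a :class:`MetaDataset` (or DataFrame with canonical columns);
    trials with a single treatment arm, or with missing true endpoints, are
    excluded from the fit with a logged warning.  A single integer ``seed``
    drives a :class:`numpy.random.SeedSequence` split across chains, so runs
    are bitwise reproducible.
    """
    scenario = Scenario(scenario)
    x_cols = getattr(data, "x_cols", ("x",))
    n_cov = len(x_cols)
    if scenario is Scenario.S2 and n_cov != 1:
        raise ValueError("Scenario S2 requires exactly one covariate")
    prep = _prepare(data, n_cov, scenario)
    q = 2 * prep["G"].shape[1]
    n_fixed = 2 * prep["F"].shape[1]
    if prior is None:
        prior = PriorSpec.default(n_fixed, q)
    if iterations <= burn_in:
        raise ValueError("iterations must exceed burn_in")

    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(chains)
    mus, Ds, sigs, gams, cids = [], [], [], [], []
    for c in range(chains):
        rng = np.random.default_rng(child_seeds[c])
        mu, D, sig, gam = _run_chain(
            prep, prior, iterations, burn_in, thinning, rng,
            store_random_effects, c,
        )
        mus.append(mu)
        Ds.append(D)
        sigs.append(sig)
        if gam is not None:
            gams.append(gam)
        cids.append(np.full(mu.shape[0], c))
    meta = {
        "seed": seed,
        "iterations": iterations,
        "burn_in": burn_in,
        "thinning": thinning,
        "chains": chains,
        "trials": prep["trials"].tolist(),
        "n_subjects": prep["n"],
    }
    if chains >= 2:
        meta["rhat"] = gelman_rubin([m for m in mus])
    return PosteriorDraws(
        scenario=scenario,
        n_covariates=n_cov,
        mu=np.concatenate(mus),
        D=np.concatenate(Ds),
        sigma=np.concatenate(sigs),
        chain_id=np.concatenate(cids),
        gamma=np.concatenate(gams) if gams else None,
        meta=meta,
    )


def gelman_rubin(chains: Sequence[np.ndarray]) -> np.ndarray:
    """Potential scale reduction factor R-hat per scalar parameter.

    ``chains`` is a sequence of (n_draws, n_params) arrays, one per chain.
    """
    arr = np.stack(chains)  # (m, n, p)
    m, n, _ = arr.shape
    chain_means = arr.mean(axis=1)
    W = arr.var(axis=1, ddof=1).mean(axis=0)
    B = n * chain_means.var(axis=0, ddof=1)
    var_hat = (n - 1) / n * W + B / n
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.sqrt(var_hat / W)


# ---------------------------------------------------------------------------
# posterior transformation into the risk measures
# ---------------------------------------------------------------------------


def draws_to_params(draws: PosteriorDraws, i: int) -> ModelParams:
    """Materialise draw ``i`` as a :class:`ModelParams`."""
    p = draws.n_covariates
    mu = draws.mu[i]
    return ModelParams(
        scenario=draws.scenario,
        alpha_s=mu[0],
        alpha_t=mu[1],
        beta_s=mu[2],
        beta_t=mu[3],
        gamma_s=mu[4 : 4 + 2 * p : 2],
        gamma_t=mu[5 : 4 + 2 * p : 2],
        delta_s=mu[4 + 2 * p :: 2],
        delta_t=mu[5 + 2 * p :: 2],
        D=draws.D[i],
        sigma=draws.sigma[i],
    )


def _effect_moments(draws: PosteriorDraws, x: float):
    """Per-draw mean and covariance of (Delta_S(x), Delta_T(x))."""
    p = draws.n_covariates
    mu = draws.mu
    if p == 0:
        m_s = mu[:, 2]
        m_t = mu[:, 3]
    else:
        d_s = mu[:, 4 + 2 * p :: 2]
        d_t = mu[:, 5 + 2 * p :: 2]
        m_s = mu[:, 2] + d_s[:, 0] * x
        m_t = mu[:, 3] + d_t[:, 0] * x
    if draws.scenario is Scenario.S1:
        covs = draws.D[:, 2:4, 2:4]
    else:
        q = 8
        w_s = np.zeros(q)
        w_t = np.zeros(q)
        w_s[2], w_s[6] = 1.0, x
        w_t[3], w_t[7] = 1.0, x
        c_ss = np.einsum("i,nij,j->n", w_s, draws.D, w_s)
        c_st = np.einsum("i,nij,j->n", w_s, draws.D, w_t)
        c_tt = np.einsum("i,nij,j->n", w_t, draws.D, w_t)
        covs = np.empty((draws.n_draws, 2, 2))
        covs[:, 0, 0] = c_ss
        covs[:, 0, 1] = covs[:, 1, 0] = c_st
        covs[:, 1, 1] = c_tt
    means = np.column_stack([m_s, m_t])
    return means, covs


def posterior_measures(
    draws: PosteriorDraws,
    x_levels: Sequence[float] = (0.0, 1.0),
    alpha: float = 0.05,
    level: float = 0.95,
    arm_counts: Optional[tuple] = None,
) -> pd.DataFrame:
    """Posterior summaries of the paradox-risk measures at each x level.

    Applies the measures to every retained draw and reports the posterior
    mean, median and equal-tailed credible interval at ``level``.  When
    ``arm_counts = (n1x, n0x)`` is given, the s-threshold is computed per
    draw as well; draws violating its precondition (dab* <= 0 or a
    nonpositive conditional variance) are counted and reported in the
    ``n_failed`` column, and an error is raised if they exceed 5%.
    """
    if draws.n_draws < 100:
        raise ValueError("need at least 100 retained draws")
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    rows = []
    for x in x_levels:
        means, covs = _effect_moments(draws, float(x))
        psi13, psi123 = psi_values(means, covs)
        for name, vals in (("psi_sp13", psi13), ("psi_sp123", psi123)):
            rows.append(
                {
                    "x": x,
                    "quantity": name,
                    "mean": vals.mean(),
                    "median": np.median(vals),
                    "lower": np.quantile(vals, lo_q),
                    "upper": np.quantile(vals, hi_q),
                    "n_failed": 0,
                }
            )
        if arm_counts is not None:
            n1x, n0x = arm_counts
            daa = covs[:, 0, 0] + draws.sigma[:, 0, 0] * (1.0 / n1x + 1.0 / n0x)
            dab = covs[:, 0, 1]
            cvar = covs[:, 1, 1] - dab**2 / daa
            ok = (dab > 0) & (cvar > 0)
            n_failed = int((~ok).sum())
            if n_failed > 0.05 * draws.n_draws:
                raise ValueError(
                    f"{n_failed}/{draws.n_draws} draws violate the s-threshold "
                    "precondition (dab* <= 0); s is not identified at this x"
                )
            s_vals = (
                means[ok, 0]
                - daa[ok] / dab[ok]
                * (ndtri(alpha) * np.sqrt(cvar[ok]) + means[ok, 1])
            )
            rows.append(
                {
                    "x": x,
                    "quantity": "s",
                    "mean": s_vals.mean(),
                    "median": np.median(s_vals),
                    "lower": np.quantile(s_vals, lo_q),
                    "upper": np.quantile(s_vals, hi_q),
                    "n_failed": n_failed,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# marginal WAIC for scenario comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WaicResult:
    waic: float
    lppd: float
    p_waic: float
    pointwise: np.ndarray  # (N,) per-trial contributions to lppd


def marginal_waic(draws: PosteriorDraws, data, n_draws: Optional[int] = None) -> WaicResult:
    """Widely applicable information criterion on the marginal likelihood.

    The random effects are integrated out analytically: per draw of
    (mu, D, sigma) each trial contributes a multivariate-normal
    log-likelihood with covariance W_i D W_i' + R_i, evaluated in O(q^3 +
    n_i) via the matrix determinant and Woodbury lemmas.  WAIC =
    -2 (lppd - p_waic) on the deviance scale; lower is better.
    """
    x_cols = getattr(data, "x_cols", ("x",))
    prep = _prepare(data, len(x_cols), draws.scenario)
    y, F, G, GG, starts, N = (
        prep["y"], prep["F"], prep["G"], prep["GG"], prep["starts"], prep["N"],
    )
    counts = np.diff(np.append(starts, prep["n"]))
    gfeat = G.shape[1]
    q = 2 * gfeat

    use = draws.n_draws if n_draws is None else min(n_draws, draws.n_draws)
    sel = np.linspace(0, draws.n_draws - 1, use).astype(int)
    logp = np.empty((use, N))
    for d_i, d in enumerate(sel):
        Amu = draws.mu[d].reshape(-1, 2)
        sigma = draws.sigma[d]
        D = draws.D[d]
        sig_inv = np.linalg.inv(sigma)
        sign, logdet_sig = np.linalg.slogdet(sigma)
        sign_D, logdet_D = np.linalg.slogdet(D)
        if sign <= 0 or sign_D <= 0 or not np.isfinite(logdet_sig + logdet_D):
            raise FloatingPointError(f"non-finite covariance in draw {d}")
        D_inv = np.linalg.inv(D)

        e0 = y - F @ Amu
        u = e0 @ sig_inv
        quad_r = _segment_sum((u * e0).sum(axis=1), starts)  # r' R^{-1} r
        B = _segment_sum(G[:, :, None] * u[:, None, :], starts).reshape(N, q)
        A = _batch_kron_2(GG, sig_inv) + D_inv[None]
        L = np.linalg.cholesky(A)
        logdet_A = 2.0 * np.log(
            np.diagonal(L, axis1=1, axis2=2)
        ).sum(axis=1)
        sol = np.linalg.solve(A, B[:, :, None])[:, :, 0]
        quad = quad_r - np.einsum("nq,nq->n", B, sol)
        logdet_V = counts * logdet_sig + logdet_D + logdet_A
        logp[d_i] = -0.5 * (2 * counts * np.log(2 * np.pi) + logdet_V + quad)

    pointwise = logsumexp(logp, axis=0) - np.log(use)
    lppd = float(pointwise.sum())
    p_waic = 0.0 if use == 1 else float(logp.var(axis=0, ddof=1).sum())
    return WaicResult(
        waic=-2.0 * (lppd - p_waic), lppd=lppd, p_waic=p_waic, pointwise=pointwise
    )


# ---------------------------------------------------------------------------
# draws serialisation (columnar text, bitwise round-trip)
# ---------------------------------------------------------------------------


def _mu_names(n_covariates: int) -> list[str]:
    names = ["alpha_S", "alpha_T", "beta_S", "beta_T"]
    for k in range(n_covariates):
        suf = "" if n_covariates == 1 else f"_{k + 1}"
        names += [f"gamma_S{suf}", f"gamma_T{suf}"]
    for k in range(n_covariates):
        suf = "" if n_covariates == 1 else f"_{k + 1}"
        names += [f"delta_S{suf}", f"delta_T{suf}"]
    return names


def write_draws(draws: PosteriorDraws, path) -> None:
    """Write retained draws as delimited text, one row per iteration."""
    from .model import re_entry_name

    q = draws.D.shape[1]
    cols = {"chain": draws.chain_id}
    for j, name in enumerate(_mu_names(draws.n_covariates)):
        cols[name] = draws.mu[:, j]
    for i in range(q):
        for j in range(i, q):
            cols[re_entry_name(i, j)] = draws.D[:, i, j]
    cols["sigma_ss"] = draws.sigma[:, 0, 0]
    cols["sigma_st"] = draws.sigma[:, 0, 1]
    cols["sigma_tt"] = draws.sigma[:, 1, 1]
    df = pd.DataFrame(cols)
    with open(path, "w") as fh:
        for key in ("seed", "iterations", "burn_in", "thinning", "chains"):
            fh.write(f"# {key}={draws.meta.get(key)}\n")
        fh.write(f"# scenario={draws.scenario.value}\n")
        fh.write(f"# n_covariates={draws.n_covariates}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_draws(path) -> PosteriorDraws:
    """Read a draws file written by :func:`write_draws`."""
    from .model import re_entry_name

    meta: dict = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val
            pos = fh.tell()
        df = pd.read_csv(fh, float_precision="round_trip")
    scenario = Scenario(meta.pop("scenario"))
    p = int(meta.pop("n_covariates"))
    q = scenario.n_random_effects
    n = len(df)
    mu = df[_mu_names(p)].to_numpy(float)
    D = np.empty((n, q, q))
    for i in range(q):
        for j in range(i, q):
            D[:, i, j] = D[:, j, i] = df[re_entry_name(i, j)].to_numpy(float)
    sigma = np.empty((n, 2, 2))
    sigma[:, 0, 0] = df["sigma_ss"]
    sigma[:, 0, 1] = sigma[:, 1, 0] = df["sigma_st"]
    sigma[:, 1, 1] = df["sigma_tt"]
    for key in ("seed", "iterations", "burn_in", "thinning", "chains"):
        if meta.get(key, "None") != "None":
            meta[key] = int(meta[key])
        else:
            meta[key] = None
    return PosteriorDraws(
        scenario=scenario,
        n_covariates=p,
        mu=mu,
        D=D,
        sigma=sigma,
        chain_id=df["chain"].to_numpy(int),
        meta=meta,
    )
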