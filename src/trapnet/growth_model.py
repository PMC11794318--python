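"""Bayesian spatial logistic growth model: fitting and kriging prediction.

The observation model is

    Y_tsx ~ Normal(mu(x; s), sigma2),
    mu(x; s) = beta(s) / (1 + exp(-(x - gamma(s)) / k)),

with Gaussian-process layers over sites,

    beta  ~ MVN(mu_beta  * 1, sigma2_beta  * C(rho_beta)),
    gamma ~ MVN(mu_gamma * 1, sigma2_gamma * C(rho_gamma)),

where ``C(rho)_ij = exp(-d_ij / rho)`` is the exponential correlation over
pairwise site distances.  The growth scale ``k`` is shared across sites and
there is no year effect: all included site-years share one curve per site.

Inference is a blocked Gibbs/Metropolis sampler written directly in
numpy/scipy.  The likelihood is linear in ``beta`` given ``(gamma, k)``, so
``beta``, the process means, the variances and the noise variance all have
conjugate updates; ``gamma`` (per site), ``k`` and the range parameters use
adaptive random-walk Metropolis steps tuned during warm-up.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_solve, cholesky, solve_triangular
from scipy.spatial.distance import cdist

from .trap_data import SiteRegistry, TrapDataset, cumulative_counts

logger = logging.getLogger(__name__)

__all__ = [
    "MCMCConfig",
    "PriorConfig",
    "GrowthParams",
    "PosteriorSamples",
    "PredictionResult",
    "logistic_mean",
    "exp_correlation",
    "fit_growth_model",
    "krige_params",
    "predict_cumulative",
]


def logistic_mean(week, beta, gamma, k):
    """Logistic growth curve ``beta / (1 + exp(-(week - gamma)/k))``.

    ``beta`` is the asymptote (maximum cumulative count), ``gamma`` the
    midpoint week where half the asymptote is reached, and ``k`` the inverse
    growth-rate scale (larger k, slower growth).  Broadcasts over array
    arguments.
    """
    k = np.asarray(k, dtype=float)
    if np.any(k <= 0):
        raise ValueError("growth scale k must be positive")
    week = np.asarray(week, dtype=float)
    z = -(week - gamma) / k
    return beta / (1.0 + np.exp(z))


def exp_correlation(registry: SiteRegistry, rho: float, jitter: float = 0.0) -> np.ndarray:
    """Exponential correlation matrix ``exp(-d_ij / rho)`` over registry sites."""
    if rho <= 0:
        raise ValueError("spatial range rho must be positive")
    D = registry.distances()
    C = np.exp(-D / rho)
    if jitter:
        C = C + jitter * np.eye(len(C))
    return C


@dataclass(frozen=True)
class PriorConfig:
    """Weakly-informative priors; None means derive the value from the data.

    Variance parameters use inverse-gamma priors with shape ``ig_shape`` and
    a data-scaled rate; ``log k`` is Normal; the spatial ranges are uniform
    on [min pairwise distance / 10, 10 * max pairwise distance].
    """

    mu_beta_loc: float | None = None
    mu_beta_scale: float | None = None
    mu_gamma_loc: float | None = None
    mu_gamma_scale: float | None = None
    ig_shape: float = 2.0
    sigma2_rate: float | None = None
    sigma2_beta_rate: float | None = None
    sigma2_gamma_rate: float | None = None
    log_k_loc: float = float(np.log(2.0))
    log_k_scale: float = 1.0
    rho_bounds: tuple[float, float] | None = None
    fix_means_zero: bool = False  # literal zero-mean process layer


@dataclass(frozen=True)
class MCMCConfig:
    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    seed: int = 0
    jitter: float = 1e-8
    rhat_warn: float = 1.05
    priors: PriorConfig = field(default_factory=PriorConfig)

    @classmethod
    def fast(cls, seed: int = 0, **kwargs) -> "MCMCConfig":
        """Reduced-cost profile for CI and sweeps."""
        kwargs.setdefault("chains", 1)
        kwargs.setdefault("warmup", 250)
        kwargs.setdefault("draws", 250)
        return cls(seed=seed, **kwargs)

    def with_seed(self, seed: int) -> "MCMCConfig":
        return replace(self, seed=int(seed))


@dataclass
class GrowthParams:
    """One parameter state (or draw) of the growth model."""

    beta: np.ndarray
    gamma: np.ndarray
    k: float
    sigma2: float
    mu_beta: float
    mu_gamma: float
    sigma2_beta: float
    sigma2_gamma: float
    rho_beta: float
    rho_gamma: float

    def __post_init__(self) -> None:
        for name in ("k", "sigma2", "sigma2_beta", "sigma2_gamma", "rho_beta", "rho_gamma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if len(self.beta) != len(self.gamma):
            raise ValueError("beta and gamma must have equal length")


@dataclass
class PosteriorSamples:
    """Stacked posterior draws plus the training-site registry.

    Arrays are (n_draws,) for scalars and (n_draws, n_train_sites) for the
    site fields, in the order of ``train_registry.site_ids``.
    """

    train_registry: SiteRegistry
    beta: np.ndarray
    gamma: np.ndarray
    k: np.ndarray
    sigma2: np.ndarray
    mu_beta: np.ndarray
    mu_gamma: np.ndarray
    sigma2_beta: np.ndarray
    sigma2_gamma: np.ndarray
    rho_beta: np.ndarray
    rho_gamma: np.ndarray
    diagnostics: dict[str, float] = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return len(self.k)

    def draw(self, i: int) -> GrowthParams:
        return GrowthParams(
            beta=self.beta[i],
            gamma=self.gamma[i],
            k=float(self.k[i]),
            sigma2=float(self.sigma2[i]),
            mu_beta=float(self.mu_beta[i]),
            mu_gamma=float(self.mu_gamma[i]),
            sigma2_beta=float(self.sigma2_beta[i]),
            sigma2_gamma=float(self.sigma2_gamma[i]),
            rho_beta=float(self.rho_beta[i]),
            rho_gamma=float(self.rho_gamma[i]),
        )

    def thin(self, max_draws: int) -> "PosteriorSamples":
        n = self.n_draws
        if n <= max_draws:
            return self
        idx = np.linspace(0, n - 1, max_draws).round().astype(int)
        return PosteriorSamples(
            train_registry=self.train_registry,
            beta=self.beta[idx],
            gamma=self.gamma[idx],
            k=self.k[idx],
            sigma2=self.sigma2[idx],
            mu_beta=self.mu_beta[idx],
            mu_gamma=self.mu_gamma[idx],
            sigma2_beta=self.sigma2_beta[idx],
            sigma2_gamma=self.sigma2_gamma[idx],
            rho_beta=self.rho_beta[idx],
            rho_gamma=self.rho_gamma[idx],
            diagnostics=dict(self.diagnostics),
        )

    def to_frame(self) -> pd.DataFrame:
        data = {
            "k": self.k,
            "sigma2": self.sigma2,
            "mu_beta": self.mu_beta,
            "mu_gamma": self.mu_gamma,
            "sigma2_beta": self.sigma2_beta,
            "sigma2_gamma": self.sigma2_gamma,
            "rho_beta": self.rho_beta,
            "rho_gamma": self.rho_gamma,
        }
        for j, sid in enumerate(self.train_registry.site_ids):
            data[f"beta[{sid}]"] = self.beta[:, j]
            data[f"gamma[{sid}]"] = self.gamma[:, j]
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _split_rhat(chains: np.ndarray) -> float:
    """Split-Rhat for a (n_chains, n_draws) array of one scalar parameter."""
    n_chains, n = chains.shape
    half = n // 2
    if half < 2:
        return float("nan")
    halves = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    m, n = halves.shape
    means = halves.mean(axis=1)
    W = halves.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W <= 0:
        return 1.0
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def _resolve_priors(
    priors: PriorConfig, y: np.ndarray, weeks: np.ndarray, totals: np.ndarray, D: np.ndarray
) -> dict:
    """Fill data-driven defaults for any prior hyperparameter left as None."""
    wmax = float(weeks.max())
    tot_mean = float(totals.mean())
    tot_sd = float(totals.std())
    offdiag = D[~np.eye(len(D), dtype=bool)]
    dmin = float(offdiag.min()) if offdiag.size else 1.0
    dmax = float(offdiag.max()) if offdiag.size else 1.0
    out = {
        "mu_beta_loc": priors.mu_beta_loc if priors.mu_beta_loc is not None else tot_mean,
        "mu_beta_scale": priors.mu_beta_scale
        if priors.mu_beta_scale is not None
        else max(3.0 * tot_sd, tot_mean, 1.0),
        "mu_gamma_loc": priors.mu_gamma_loc
        if priors.mu_gamma_loc is not None
        else wmax / 2.0,
        "mu_gamma_scale": priors.mu_gamma_scale
        if priors.mu_gamma_scale is not None
        else max(wmax, 2.0),
        "ig_shape": priors.ig_shape,
        "sigma2_rate": priors.sigma2_rate
        if priors.sigma2_rate is not None
        else max(0.01 * float(np.var(y)), 1e-4),
        "sigma2_beta_rate": priors.sigma2_beta_rate
        if priors.sigma2_beta_rate is not None
        else max(float(np.var(totals)), 1.0),
        "sigma2_gamma_rate": priors.sigma2_gamma_rate
        if priors.sigma2_gamma_rate is not None
        else max((wmax / 4.0) ** 2, 0.5),
        "log_k_loc": priors.log_k_loc,
        "log_k_scale": priors.log_k_scale,
        "rho_bounds": priors.rho_bounds
        if priors.rho_bounds is not None
        else (max(dmin / 10.0, 1e-3), 10.0 * max(dmax, 1e-2)),
        "fix_means_zero": priors.fix_means_zero,
    }
    return out


class _ChainState:
    __slots__ = (
        "beta", "gamma", "log_k", "sigma2", "mu_beta", "mu_gamma",
        "s2b", "s2g", "rho_b", "rho_g",
        "cholB", "invB", "logdetB", "cholG", "invG", "logdetG",
    )


def _corr_factor(D: np.ndarray, rho: float, jitter: float):
    C = np.exp(-D / rho)
    C[np.diag_indices_from(C)] += jitter
    L = cholesky(C, lower=True)
    Linv = solve_triangular(L, np.eye(len(C)), lower=True)
    inv = Linv.T @ Linv
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    return L, inv, logdet


def _init_state(rng, pr, D, jitter, site_idx, weeks, y, n_sites) -> _ChainState:
    st = _ChainState()
    totals = np.array(
        [y[site_idx == s].max() if np.any(site_idx == s) else 1.0 for s in range(n_sites)]
    )
    st.beta = np.maximum(totals, 0.5) * np.exp(0.05 * rng.standard_normal(n_sites))
    # midpoint guess: first week where the series crosses half its total
    gam0 = np.empty(n_sites)
    for s in range(n_sites):
        ys, ws = y[site_idx == s], weeks[site_idx == s]
        half = 0.5 * ys.max() if ys.size else 0.0
        above = ws[ys >= half] if ys.size else np.array([pr["mu_gamma_loc"]])
        gam0[s] = float(above.min()) if above.size else pr["mu_gamma_loc"]
    st.gamma = gam0 + 0.3 * rng.standard_normal(n_sites)
    st.log_k = float(np.log(1.5) + 0.2 * rng.standard_normal())
    st.sigma2 = max(0.1 * float(np.var(y)), 1e-3)
    st.mu_beta = 0.0 if pr["fix_means_zero"] else float(st.beta.mean())
    st.mu_gamma = 0.0 if pr["fix_means_zero"] else float(st.gamma.mean())
    st.s2b = max(float(np.var(st.beta)), 1.0)
    st.s2g = max(float(np.var(st.gamma)), 0.25)
    lo, hi = pr["rho_bounds"]
    st.rho_b = float(np.sqrt(lo * hi))
    st.rho_g = float(np.sqrt(lo * hi))
    st.cholB, st.invB, st.logdetB = _corr_factor(D, st.rho_b, jitter)
    st.cholG, st.invG, st.logdetG = _corr_factor(D, st.rho_g, jitter)
    return st


def _run_chain(rng, pr, D, jitter, site_idx, weeks, y, n_sites, warmup, draws, cells_by_site):
    st = _init_state(rng, pr, D, jitter, site_idx, weeks, y, n_sites)
    n = len(y)
    ones = np.ones(n_sites)
    # adaptive RW step sizes
    step_g = np.full(n_sites, 0.5)
    step_k = 0.2
    step_rb = 0.5
    step_rg = 0.5
    acc_g = np.zeros(n_sites)
    acc_k = acc_rb = acc_rg = 0.0
    window = 25

    ig_a = pr["ig_shape"]
    lo_rho, hi_rho = pr["rho_bounds"]
    log_lo, log_hi = np.log(lo_rho), np.log(hi_rho)

    out = {name: [] for name in (
        "beta", "gamma", "k", "sigma2", "mu_beta", "mu_gamma",
        "s2b", "s2g", "rho_b", "rho_g")}

    def mu_all(gamma, k):
        return st.beta[site_idx] / (1.0 + np.exp(-(weeks - gamma[site_idx]) / k))

    total_iters = warmup + draws
    for it in range(total_iters):
        k = float(np.exp(st.log_k))

        # -- gamma: per-site random-walk Metropolis, MVN prior conditional
        Pg = st.invG / st.s2g
        r = st.gamma - st.mu_gamma
        for s in range(n_sites):
            ws, ys = cells_by_site[s]
            g_old = st.gamma[s]
            g_new = g_old + step_g[s] * rng.standard_normal()
            mu_old = st.beta[s] / (1.0 + np.exp(-(ws - g_old) / k))
            mu_new = st.beta[s] / (1.0 + np.exp(-(ws - g_new) / k))
            dll = -0.5 / st.sigma2 * (
                np.sum((ys - mu_new) ** 2) - np.sum((ys - mu_old) ** 2)
            )
            r_old = r[s]
            r_new = g_new - st.mu_gamma
            cross = Pg[s] @ r - Pg[s, s] * r_old
            dlp = -0.5 * Pg[s, s] * (r_new**2 - r_old**2) - cross * (r_new - r_old)
            if np.log(rng.random()) < dll + dlp:
                st.gamma[s] = g_new
                r[s] = r_new
                acc_g[s] += 1

        # -- k: random walk on log k
        log_k_new = st.log_k + step_k * rng.standard_normal()
        k_new = float(np.exp(log_k_new))
        mu_cur = mu_all(st.gamma, k)
        mu_prop = mu_all(st.gamma, k_new)
        dll = -0.5 / st.sigma2 * (np.sum((y - mu_prop) ** 2) - np.sum((y - mu_cur) ** 2))
        dlp = -0.5 / pr["log_k_scale"] ** 2 * (
            (log_k_new - pr["log_k_loc"]) ** 2 - (st.log_k - pr["log_k_loc"]) ** 2
        )
        if np.log(rng.random()) < dll + dlp:
            st.log_k = log_k_new
            k = k_new
            mu_cur = mu_prop
            acc_k += 1

        # -- beta: conjugate MVN given logistic weights g
        g = 1.0 / (1.0 + np.exp(-(weeks - st.gamma[site_idx]) / k))
        d = np.bincount(site_idx, weights=g * g, minlength=n_sites)
        h = np.bincount(site_idx, weights=g * y, minlength=n_sites)
        Pb = st.invB / st.s2b
        Q = Pb + np.diag(d / st.sigma2)
        rhs = Pb @ (st.mu_beta * ones) + h / st.sigma2
        LQ = cholesky(Q, lower=True)
        mean_b = cho_solve((LQ, True), rhs)
        z = rng.standard_normal(n_sites)
        st.beta = mean_b + solve_triangular(LQ, z, lower=True, trans="T")

        # -- sigma2: conjugate inverse-gamma
        resid = y - st.beta[site_idx] * g
        a_post = ig_a + 0.5 * n
        b_post = pr["sigma2_rate"] + 0.5 * float(resid @ resid)
        st.sigma2 = b_post / rng.gamma(a_post)

        # -- process means (conjugate) unless literal zero-mean layer
        if not pr["fix_means_zero"]:
            q1 = float(ones @ st.invB @ ones) / st.s2b
            qb = float(ones @ st.invB @ st.beta) / st.s2b
            prec = 1.0 / pr["mu_beta_scale"] ** 2 + q1
            mean = (pr["mu_beta_loc"] / pr["mu_beta_scale"] ** 2 + qb) / prec
            st.mu_beta = mean + rng.standard_normal() / np.sqrt(prec)

            q1g = float(ones @ st.invG @ ones) / st.s2g
            qg = float(ones @ st.invG @ st.gamma) / st.s2g
            precg = 1.0 / pr["mu_gamma_scale"] ** 2 + q1g
            meang = (pr["mu_gamma_loc"] / pr["mu_gamma_scale"] ** 2 + qg) / precg
            st.mu_gamma = meang + rng.standard_normal() / np.sqrt(precg)

        # -- process variances: conjugate inverse-gamma
        db = st.beta - st.mu_beta
        qf_b = float(db @ st.invB @ db)
        st.s2b = (pr["sigma2_beta_rate"] + 0.5 * qf_b) / rng.gamma(ig_a + 0.5 * n_sites)
        dg = st.gamma - st.mu_gamma
        qf_g = float(dg @ st.invG @ dg)
        st.s2g = (pr["sigma2_gamma_rate"] + 0.5 * qf_g) / rng.gamma(ig_a + 0.5 * n_sites)

        # -- spatial ranges: random walk on log rho, uniform prior on rho
        log_rb_new = np.log(st.rho_b) + step_rb * rng.standard_normal()
        if log_lo <= log_rb_new <= log_hi:
            rho_new = float(np.exp(log_rb_new))
            try:
                cN, iN, ldN = _corr_factor(D, rho_new, jitter)
            except np.linalg.LinAlgError:
                cN = None
            if cN is not None:
                qf_new = float(db @ iN @ db)
                lt_new = -0.5 * ldN - 0.5 * qf_new / st.s2b + log_rb_new
                lt_old = -0.5 * st.logdetB - 0.5 * qf_b / st.s2b + np.log(st.rho_b)
                if np.log(rng.random()) < lt_new - lt_old:
                    st.rho_b = rho_new
                    st.cholB, st.invB, st.logdetB = cN, iN, ldN
                    acc_rb += 1

        log_rg_new = np.log(st.rho_g) + step_rg * rng.standard_normal()
        if log_lo <= log_rg_new <= log_hi:
            rho_new = float(np.exp(log_rg_new))
            try:
                cN, iN, ldN = _corr_factor(D, rho_new, jitter)
            except np.linalg.LinAlgError:
                cN = None
            if cN is not None:
                qf_new = float(dg @ iN @ dg)
                lt_new = -0.5 * ldN - 0.5 * qf_new / st.s2g + log_rg_new
                lt_old = -0.5 * st.logdetG - 0.5 * qf_g / st.s2g + np.log(st.rho_g)
                if np.log(rng.random()) < lt_new - lt_old:
                    st.rho_g = rho_new
                    st.cholG, st.invG, st.logdetG = cN, iN, ldN
                    acc_rg += 1

        # -- warm-up step-size adaptation
        if it < warmup and (it + 1) % window == 0:
            step_g *= np.exp(0.6 * (acc_g / window - 0.4))
            step_k *= np.exp(0.6 * (acc_k / window - 0.4))
            step_rb *= np.exp(0.6 * (acc_rb / window - 0.4))
            step_rg *= np.exp(0.6 * (acc_rg / window - 0.4))
            np.clip(step_g, 1e-3, 10.0, out=step_g)
            step_k = float(np.clip(step_k, 1e-3, 2.0))
            step_rb = float(np.clip(step_rb, 1e-3, 3.0))
            step_rg = float(np.clip(step_rg, 1e-3, 3.0))
            acc_g[:] = 0
            acc_k = acc_rb = acc_rg = 0.0

        if it >= warmup:
            out["beta"].append(st.beta.copy())
            out["gamma"].append(st.gamma.copy())
            out["k"].append(np.exp(st.log_k))
            out["sigma2"].append(st.sigma2)
            out["mu_beta"].append(st.mu_beta)
            out["mu_gamma"].append(st.mu_gamma)
            out["s2b"].append(st.s2b)
            out["s2g"].append(st.s2g)
            out["rho_b"].append(st.rho_b)
            out["rho_g"].append(st.rho_g)

    return {name: np.asarray(vals) for name, vals in out.items()}


def fit_growth_model(
    ds: TrapDataset,
    train_sites: Iterable[int],
    years: Iterable[int],
    mcmc_config: MCMCConfig | None = None,
) -> PosteriorSamples:
    """Fit the spatial logistic growth model on the given sites and years.

    Pools all included site-years into one likelihood (no year effect).
    The response is the cumulative count; the dataset must have no
    flagged-missing cells.  Returns posterior draws from all chains with
    split-Rhat diagnostics; poor convergence emits a warning, not an error.
    """
    config = mcmc_config or MCMCConfig()
    train_ids = sorted(int(s) for s in train_sites)
    years = set(int(y) for y in years)
    if len(train_ids) < 2:
        raise ValueError("need at least 2 training sites for the spatial layer")
    registry = ds.registry.subset(train_ids)

    site_pos = {sid: i for i, sid in enumerate(registry.site_ids)}
    rows_s, rows_w, rows_y = [], [], []
    for series in cumulative_counts(ds):
        if series.year in years and series.site_id in site_pos:
            for w, v in enumerate(series.values, start=1):
                rows_s.append(site_pos[series.site_id])
                rows_w.append(w)
                rows_y.append(v)
    if not rows_y:
        raise ValueError("no observations for the requested sites/years")
    site_idx = np.asarray(rows_s, dtype=int)
    weeks = np.asarray(rows_w, dtype=float)
    y = np.asarray(rows_y, dtype=float)
    for s in range(len(train_ids)):
        n_weeks = len(np.unique(weeks[site_idx == s]))
        if n_weeks and n_weeks < 3:
            raise ValueError(
                f"site {registry.site_ids[s]} has fewer than 3 weeks of data"
            )

    D = registry.distances()
    totals = np.array(
        [y[site_idx == s].max() if np.any(site_idx == s) else 1.0
         for s in range(len(train_ids))]
    )
    pr = _resolve_priors(config.priors, y, weeks, totals, D)
    cells_by_site = [
        (weeks[site_idx == s], y[site_idx == s]) for s in range(len(train_ids))
    ]

    ss = np.random.SeedSequence(config.seed)
    chain_out = []
    for child in ss.spawn(config.chains):
        rng = np.random.default_rng(child)
        chain_out.append(
            _run_chain(
                rng, pr, D, config.jitter, site_idx, weeks, y,
                len(train_ids), config.warmup, config.draws, cells_by_site,
            )
        )

    stacked = {
        name: np.concatenate([c[name] for c in chain_out], axis=0)
        for name in chain_out[0]
    }
    diagnostics: dict[str, float] = {}
    for name in ("k", "sigma2", "mu_beta", "mu_gamma", "s2b", "s2g", "rho_b", "rho_g"):
        per_chain = np.stack([c[name] for c in chain_out])
        diagnostics[f"rhat_{name}"] = _split_rhat(per_chain)
    worst = np.nanmax(list(diagnostics.values())) if diagnostics else float("nan")
    diagnostics["rhat_max"] = float(worst)
    if np.isfinite(worst) and worst > config.rhat_warn:
        warnings.warn(
            f"MCMC convergence suspect: max split-Rhat {worst:.3f} > {config.rhat_warn}",
            RuntimeWarning,
            stacklevel=2,
        )

    return PosteriorSamples(
        train_registry=registry,
        beta=stacked["beta"],
        gamma=stacked["gamma"],
        k=stacked["k"],
        sigma2=stacked["sigma2"],
        mu_beta=stacked["mu_beta"],
        mu_gamma=stacked["mu_gamma"],
        sigma2_beta=stacked["s2b"],
        sigma2_gamma=stacked["s2g"],
        rho_beta=stacked["rho_b"],
        rho_gamma=stacked["rho_g"],
        diagnostics=diagnostics,
    )


_COINCIDENT_TOL = 1e-9


def krige_params(
    post: PosteriorSamples,
    targets: SiteRegistry,
    registry_train: SiteRegistry | None = None,
    jitter: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray]:
    """Simple-kriging interpolation of the site fields at target locations.

    Per draw d and target s*:

        beta_d(s*) = mu_beta_d + r' C_d^{-1} (beta_d - mu_beta_d 1)

    with ``r_i = exp(-||s* - s_i|| / rho_beta_d)``; same form for gamma.
    Targets coincident with a training site get that site's sampled value
    exactly.  Returns (beta_star, gamma_star), each (n_draws, n_targets).
    """
    train = registry_train or post.train_registry
    if post.n_draws < 1:
        raise ValueError("posterior is empty")
    Dtrain = train.distances()
    Dcross = cdist(targets.coords, train.coords)
    coincident = Dcross.min(axis=1) < _COINCIDENT_TOL
    if coincident.any():
        logger.info(
            "kriging targets coincide with training sites at %d location(s); "
            "returning sampled parameters exactly", int(coincident.sum()),
        )
    nearest = Dcross.argmin(axis=1)

    n_draws, n_targets = post.n_draws, len(targets.site_ids)
    beta_star = np.empty((n_draws, n_targets))
    gamma_star = np.empty((n_draws, n_targets))
    eye = jitter * np.eye(len(train.site_ids))
    for d in range(n_draws):
        for arr_out, fld, mu, rho in (
            (beta_star, post.beta[d], post.mu_beta[d], post.rho_beta[d]),
            (gamma_star, post.gamma[d], post.mu_gamma[d], post.rho_gamma[d]),
        ):
            C = np.exp(-Dtrain / rho) + eye
            r = np.exp(-Dcross / rho)
            w = np.linalg.solve(C, fld - mu)
            arr_out[d] = mu + r @ w
        if coincident.any():
            beta_star[d, coincident] = post.beta[d][nearest[coincident]]
            gamma_star[d, coincident] = post.gamma[d][nearest[coincident]]
    return beta_star, gamma_star


@dataclass
class PredictionResult:
    """Posterior-mean cumulative predictions with central 95% intervals."""

    site_ids: tuple[int, ...]
    weeks: np.ndarray
    mean: np.ndarray   # (n_sites, n_weeks)
    lower: np.ndarray
    upper: np.ndarray

    def value(self, site_id: int, week: int, clip_zero: bool = True) -> float:
        i = self.site_ids.index(int(site_id))
        j = int(np.where(self.weeks == week)[0][0])
        v = float(self.mean[i, j])
        return max(v, 0.0) if clip_zero else v


def predict_cumulative(
    post: PosteriorSamples,
    targets: SiteRegistry,
    weeks: Sequence[int],
) -> PredictionResult:
    """Predict cumulative counts at target sites for the given weeks.

    The point prediction is the posterior mean over draws of the logistic
    curve evaluated at kriged (beta*, gamma*) with the draw's shared k.
    """
    weeks = np.asarray(sorted(set(int(w) for w in weeks)))
    if weeks.size == 0:
        raise ValueError("empty week range")
    beta_star, gamma_star = krige_params(post, targets)
    # (draws, sites, weeks)
    curves = logistic_mean(
        weeks[None, None, :], beta_star[:, :, None], gamma_star[:, :, None],
        post.k[:, None, None],
    )
    return PredictionResult(
        site_ids=targets.site_ids,
        weeks=weeks,
        mean=curves.mean(axis=0),
        lower=np.quantile(curves, 0.025, axis=0),
        upper=np.quantile(curves, 0.975, axis=0),
    )
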