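"""Hierarchical Bayesian psychophysical models.

Two competing models for the relation between normalised stimulus intensity
x (0-1) and normalised rating y = rating/100:

* power law:  y_ij ~ N(b0_j * x^(b1_j), sigma_e^2)
* linear:     y_ij ~ N(beta0_j + beta1_j * x, sigma_e^2)

Both have participant-level intercepts/exponents (slopes) decomposed into a
population effect plus a participant deviation u_j.  Priors: the population
intercept is N(0, 5); the population exponent is a normal(1, 0.5) truncated
to positive support; the population slope of the linear model is N(0, 1);
all standard deviations carry half-Student-t(3, 0, 2.5) priors; the linear
model's random intercept/slope pair is bivariate normal with an LKJ(1)
(uniform) prior on the correlation.

Sampling uses an affine-invariant ensemble MCMC sampler on the unconstrained
scale (log for standard deviations and the positive exponent, atanh for the
correlation) with a non-centered parameterization of the participant effects.
The "chains x draws" interface mirrors conventional MCMC reporting: the
ensemble is run long enough to retain ``total_draws`` post-warmup draws, and
walkers play the role of chains in the split-R-hat diagnostic.  The
unconstrained joint log density (likelihood + priors + Jacobians) is exposed
on the returned :class:`PosteriorSamples` — it is exactly the quantity the
bridge-sampling estimator needs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import arviz as az
import emcee
import numpy as np
from scipy import stats
from scipy.special import log_ndtr

from .stimuli import StimulusSet
from .synthetic import RatingDataset

__all__ = [
    "PowerModelSpec",
    "LinearModelSpec",
    "PosteriorSamples",
    "ConvergenceWarning",
    "power_log_density",
    "linear_log_density",
    "log_prior",
    "fit",
    "prepare_model_data",
]

_LOG_2PI = np.log(2.0 * np.pi)


class ConvergenceWarning(UserWarning):
    """Raised (as a warning) when R-hat exceeds the reporting threshold."""


# ---------------------------------------------------------------------------
# pointwise densities (the likelihood kernels of the two models)


def power_log_density(
    y: float, x: float, b0j: float, b1j: float, sigma_e: float
) -> float:
    """Normal log density of one observation under the power-law mean."""
    if sigma_e <= 0:
        raise ValueError("sigma_e must be positive")
    if x <= 0:
        raise ValueError("x must be positive")
    mu = b0j * x**b1j
    return float(-0.5 * ((y - mu) / sigma_e) ** 2 - np.log(sigma_e) - 0.5 * _LOG_2PI)


def linear_log_density(
    y: float, x: float, beta0j: float, beta1j: float, sigma_e: float
) -> float:
    """Normal log density of one observation under the linear mean."""
    if sigma_e <= 0:
        raise ValueError("sigma_e must be positive")
    mu = beta0j + beta1j * x
    return float(-0.5 * ((y - mu) / sigma_e) ** 2 - np.log(sigma_e) - 0.5 * _LOG_2PI)


# ---------------------------------------------------------------------------
# prior building blocks


def _norm_logpdf(v, mean, sd):
    return -0.5 * ((v - mean) / sd) ** 2 - np.log(sd) - 0.5 * _LOG_2PI


def _half_t_logpdf(sigma, df=3.0, scale=2.5):
    """half-Student-t(df, 0, scale); -inf for sigma <= 0."""
    from scipy.special import gammaln

    sigma = np.asarray(sigma, dtype=float)
    const = (
        np.log(2.0)
        + gammaln((df + 1.0) / 2.0)
        - gammaln(df / 2.0)
        - 0.5 * np.log(df * np.pi)
        - np.log(scale)
    )
    s = np.where(sigma > 0, sigma, 1.0) / scale
    out = np.where(
        sigma > 0,
        const - 0.5 * (df + 1.0) * np.log1p(s * s / df),
        -np.inf,
    )
    return out if out.ndim else float(out)


def _truncnorm_pos_logpdf(v, mean, sd):
    """Normal(mean, sd) truncated to v > 0 (normalised)."""
    v = np.asarray(v, dtype=float)
    logz = log_ndtr(mean / sd)  # P(X > 0) for X ~ N(mean, sd)
    out = np.where(
        v > 0,
        stats.norm.logpdf(np.where(v > 0, v, 1.0), mean, sd) - logz,
        -np.inf,
    )
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# model data


@dataclass(frozen=True)
class ModelData:
    """Arrays the likelihood consumes: y = rating/100, x = normalised
    intensity, pid = 0-based participant index per observation."""

    y: np.ndarray
    x: np.ndarray
    pid: np.ndarray
    n_participants: int

    @property
    def n_obs(self) -> int:
        return self.y.size


def prepare_model_data(
    dataset: RatingDataset, stimulus_set: StimulusSet | None = None
) -> ModelData:
    """Map a preprocessed (standard-scale, positive-response) dataset onto
    the modelling scale."""
    ss = stimulus_set or dataset.stimulus_set
    df = dataset.trials
    resp = df["response"].to_numpy(dtype=float)
    if np.any(resp <= 0):
        raise ValueError("responses must be positive (floor zeros first)")
    xmap = ss.normalized()
    x = df["stimulus_id"].map(xmap).to_numpy(dtype=float)
    pids = {p: i for i, p in enumerate(sorted(df["participant_id"].unique()))}
    pid = df["participant_id"].map(pids).to_numpy(dtype=np.int64)
    return ModelData(y=resp / 100.0, x=x, pid=pid, n_participants=len(pids))


# ---------------------------------------------------------------------------
# model specifications


@dataclass(frozen=True)
class PowerModelSpec:
    """Hierarchical power law; see module docstring for priors."""

    prior_b0_sd: float = 5.0
    prior_b1_mean: float = 1.0
    prior_b1_sd: float = 0.5
    sigma_prior_df: float = 3.0
    sigma_prior_scale: float = 2.5

    name: str = "power"
    population_params = ("b0", "b1", "sigma_u0", "sigma_u1", "sigma_e")

    def n_dim(self, n_participants: int) -> int:
        return 5 + 2 * n_participants

    # unconstrained layout: [b0, log b1, log s_u0, log s_u1, log s_e,
    #                        b0_1..b0_J, b1_1..b1_J]  (centered effects)
    def unpack(self, theta: np.ndarray, J: int) -> dict[str, np.ndarray]:
        t = np.atleast_2d(theta)
        return {
            "b0": t[:, 0],
            "b1": np.exp(t[:, 1]),
            "sigma_u0": np.exp(t[:, 2]),
            "sigma_u1": np.exp(t[:, 3]),
            "sigma_e": np.exp(t[:, 4]),
            "e0": t[:, 5 : 5 + J],
            "e1": t[:, 5 + J : 5 + 2 * J],
        }

    def participant_effects(self, p: dict[str, np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
        return p["e0"], p["e1"]

    def mean_function(self, e0: np.ndarray, e1: np.ndarray, x: np.ndarray) -> np.ndarray:
        # x^e1 via exp(e1 * log x), exponent clipped against overflow in
        # far prior tails
        logx = np.log(x)
        return e0 * np.exp(np.clip(e1 * logx[None, :], -60.0, 60.0))

    def log_prior_unconstrained(self, theta: np.ndarray, J: int) -> np.ndarray:
        t = np.atleast_2d(theta)
        p = self.unpack(t, J)
        lp = _norm_logpdf(p["b0"], 0.0, self.prior_b0_sd)
        lp = lp + _truncnorm_pos_logpdf(p["b1"], self.prior_b1_mean, self.prior_b1_sd)
        for key in ("sigma_u0", "sigma_u1", "sigma_e"):
            lp = lp + _half_t_logpdf(p[key], self.sigma_prior_df, self.sigma_prior_scale)
        # centered participant effects: b0j ~ N(b0, s_u0), b1j ~ N(b1, s_u1)
        d0 = (p["e0"] - p["b0"][:, None]) / p["sigma_u0"][:, None]
        d1 = (p["e1"] - p["b1"][:, None]) / p["sigma_u1"][:, None]
        lp = lp - 0.5 * np.sum(d0**2 + d1**2, axis=1) - J * _LOG_2PI
        lp = lp - J * (np.log(p["sigma_u0"]) + np.log(p["sigma_u1"]))
        # Jacobians of the log transforms: b1 and the three sigmas
        lp = lp + t[:, 1] + t[:, 2] + t[:, 3] + t[:, 4]
        return lp

    def initial_guess(self, data: ModelData, rng: np.random.Generator) -> np.ndarray:
        if data.n_obs == 0:  # prior-only run
            return np.concatenate(
                [[0.5, 0.0, np.log(0.5), np.log(0.5), np.log(0.5)],
                 np.full(2 * data.n_participants, 0.5)]
            )
        # per-participant log-log least squares start
        ly, lx = np.log(np.maximum(data.y, 1e-6)), np.log(data.x)
        slope, intercept = np.polyfit(lx, ly, 1)
        b1 = float(np.clip(slope, 0.05, 5.0))
        b0 = float(np.clip(np.exp(intercept), 1e-3, 5.0))
        e0 = np.full(data.n_participants, b0)
        e1 = np.full(data.n_participants, b1)
        for j in range(data.n_participants):
            m = data.pid == j
            if m.sum() >= 3:
                sj, ij = np.polyfit(lx[m], ly[m], 1)
                e1[j] = float(np.clip(sj, 0.05, 5.0))
                e0[j] = float(np.clip(np.exp(ij), 1e-3, 5.0))
        resid_sd = float(np.std(data.y - e0[data.pid] * data.x ** e1[data.pid])) or 0.05
        theta0 = np.concatenate(
            [
                [np.mean(e0), np.log(np.mean(e1)),
                 np.log(np.std(e0) + 0.02), np.log(np.std(e1) + 0.02),
                 np.log(max(resid_sd, 1e-3))],
                e0,
                e1,
            ]
        )
        return theta0

    def sample_population_prior(self, n: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
        """Direct draws from the stated population-level priors."""
        lo = -self.prior_b1_mean / self.prior_b1_sd
        return {
            "b0": rng.normal(0.0, self.prior_b0_sd, n),
            "b1": stats.truncnorm.ppf(
                rng.random(n), lo, np.inf, loc=self.prior_b1_mean, scale=self.prior_b1_sd
            ),
            "sigma_u0": np.abs(stats.t.ppf(0.5 + 0.5 * rng.random(n), self.sigma_prior_df))
            * self.sigma_prior_scale,
            "sigma_u1": np.abs(stats.t.ppf(0.5 + 0.5 * rng.random(n), self.sigma_prior_df))
            * self.sigma_prior_scale,
            "sigma_e": np.abs(stats.t.ppf(0.5 + 0.5 * rng.random(n), self.sigma_prior_df))
            * self.sigma_prior_scale,
        }


@dataclass(frozen=True)
class LinearModelSpec:
    """Hierarchical linear model with correlated random effects."""

    prior_beta0_sd: float = 5.0
    prior_beta1_sd: float = 1.0
    sigma_prior_df: float = 3.0
    sigma_prior_scale: float = 2.5

    name: str = "linear"
    population_params = ("beta0", "beta1", "sigma_u0", "sigma_u1", "sigma_e", "rho")

    def n_dim(self, n_participants: int) -> int:
        return 6 + 2 * n_participants

    # layout: [beta0, beta1, log s_u0, log s_u1, log s_e, atanh rho,
    #          beta0_1..beta0_J, beta1_1..beta1_J]  (centered effects)
    def unpack(self, theta: np.ndarray, J: int) -> dict[str, np.ndarray]:
        t = np.atleast_2d(theta)
        return {
            "beta0": t[:, 0],
            "beta1": t[:, 1],
            "sigma_u0": np.exp(t[:, 2]),
            "sigma_u1": np.exp(t[:, 3]),
            "sigma_e": np.exp(t[:, 4]),
            "rho": np.tanh(t[:, 5]),
            "e0": t[:, 6 : 6 + J],
            "e1": t[:, 6 + J : 6 + 2 * J],
        }

    def participant_effects(self, p: dict[str, np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
        return p["e0"], p["e1"]

    def mean_function(self, e0: np.ndarray, e1: np.ndarray, x: np.ndarray) -> np.ndarray:
        return e0 + e1 * x[None, :]

    def log_prior_unconstrained(self, theta: np.ndarray, J: int) -> np.ndarray:
        t = np.atleast_2d(theta)
        p = self.unpack(t, J)
        lp = _norm_logpdf(p["beta0"], 0.0, self.prior_beta0_sd)
        lp = lp + _norm_logpdf(p["beta1"], 0.0, self.prior_beta1_sd)
        for key in ("sigma_u0", "sigma_u1", "sigma_e"):
            lp = lp + _half_t_logpdf(p[key], self.sigma_prior_df, self.sigma_prior_scale)
        # centered correlated effects: (beta0j, beta1j) ~ MVN with Sigma
        # built from sigma_u0, sigma_u1 and rho
        rho = p["rho"]
        omr2 = np.maximum(1.0 - rho**2, 1e-12)
        d0 = (p["e0"] - p["beta0"][:, None]) / p["sigma_u0"][:, None]
        d1 = (p["e1"] - p["beta1"][:, None]) / p["sigma_u1"][:, None]
        quad = (d0**2 - 2.0 * rho[:, None] * d0 * d1 + d1**2) / omr2[:, None]
        lp = lp - 0.5 * np.sum(quad, axis=1) - J * _LOG_2PI
        lp = lp - J * (
            np.log(p["sigma_u0"]) + np.log(p["sigma_u1"]) + 0.5 * np.log(omr2)
        )
        # LKJ(1) on a 2x2 correlation matrix is uniform on rho in (-1, 1)
        lp = lp - np.log(2.0)
        # Jacobians: three log-sigmas and atanh(rho)
        lp = lp + t[:, 2] + t[:, 3] + t[:, 4] + np.log(omr2)
        return lp

    def initial_guess(self, data: ModelData, rng: np.random.Generator) -> np.ndarray:
        if data.n_obs == 0:  # prior-only run
            return np.concatenate(
                [[0.0, 0.0, np.log(0.5), np.log(0.5), np.log(0.5), 0.0],
                 np.zeros(2 * data.n_participants)]
            )
        slope, intercept = np.polyfit(data.x, data.y, 1)
        e0 = np.full(data.n_participants, float(intercept))
        e1 = np.full(data.n_participants, float(slope))
        for j in range(data.n_participants):
            m = data.pid == j
            if m.sum() >= 3:
                sj, ij = np.polyfit(data.x[m], data.y[m], 1)
                e0[j], e1[j] = float(ij), float(sj)
        resid_sd = float(np.std(data.y - (e0[data.pid] + e1[data.pid] * data.x))) or 0.05
        theta0 = np.concatenate(
            [
                [np.mean(e0), np.mean(e1), np.log(np.std(e0) + 0.02),
                 np.log(np.std(e1) + 0.02), np.log(max(resid_sd, 1e-3)), 0.0],
                e0,
                e1,
            ]
        )
        return theta0

    def sample_population_prior(self, n: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
        return {
            "beta0": rng.normal(0.0, self.prior_beta0_sd, n),
            "beta1": rng.normal(0.0, self.prior_beta1_sd, n),
            "sigma_u0": np.abs(stats.t.ppf(0.5 + 0.5 * rng.random(n), self.sigma_prior_df))
            * self.sigma_prior_scale,
            "sigma_u1": np.abs(stats.t.ppf(0.5 + 0.5 * rng.random(n), self.sigma_prior_df))
            * self.sigma_prior_scale,
            "sigma_e": np.abs(stats.t.ppf(0.5 + 0.5 * rng.random(n), self.sigma_prior_df))
            * self.sigma_prior_scale,
            "rho": rng.uniform(-1.0, 1.0, n),
        }


ModelSpec = PowerModelSpec | LinearModelSpec


def log_prior(spec: ModelSpec, params: dict[str, float]) -> float:
    """Log prior density of a natural-scale population parameter dict.

    Participant deviations (z scores) may be supplied under ``z0``/``z1``.
    Returns -inf outside the support (negative sigmas, non-positive power
    exponent, |rho| >= 1).
    """
    lp = 0.0
    if isinstance(spec, PowerModelSpec):
        lp += stats.norm.logpdf(params["b0"], 0.0, spec.prior_b0_sd)
        lp += _truncnorm_pos_logpdf(params["b1"], spec.prior_b1_mean, spec.prior_b1_sd)
    else:
        lp += stats.norm.logpdf(params["beta0"], 0.0, spec.prior_beta0_sd)
        lp += stats.norm.logpdf(params["beta1"], 0.0, spec.prior_beta1_sd)
        rho = params.get("rho", 0.0)
        lp += -np.log(2.0) if -1.0 < rho < 1.0 else -np.inf
    for key in ("sigma_u0", "sigma_u1", "sigma_e"):
        lp += _half_t_logpdf(params[key], spec.sigma_prior_df, spec.sigma_prior_scale)
    for key in ("z0", "z1"):
        if key in params:
            z = np.asarray(params[key], dtype=float)
            lp += float(np.sum(stats.norm.logpdf(z)))
    return float(lp)


# ---------------------------------------------------------------------------
# posterior container


@dataclass
class PosteriorSamples:
    """MCMC draws plus everything downstream stages need.

    ``draws`` holds natural-scale population parameters with shape
    (chains, draws_per_chain); ``theta`` the unconstrained vectors
    (chains, draws_per_chain, ndim).  ``log_posterior`` evaluates the
    unnormalised joint (likelihood + priors + Jacobians) on unconstrained
    vectors — the bridge-sampling input.  ``pointwise_loglik`` is
    (total draws, n_obs).
    """

    spec: ModelSpec
    data: ModelData
    draws: dict[str, np.ndarray]
    theta: np.ndarray
    pointwise_loglik: np.ndarray
    log_posterior: Callable[[np.ndarray], np.ndarray]
    rhat: dict[str, float]
    ess: dict[str, float]
    converged: bool
    settings: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.theta.shape[0] * self.theta.shape[1]

    def flat(self, name: str) -> np.ndarray:
        return self.draws[name].reshape(-1)

    def flat_theta(self) -> np.ndarray:
        return self.theta.reshape(-1, self.theta.shape[-1])

    def summary(self) -> "pd.DataFrame":  # noqa: F821
        import pandas as pd

        rows = []
        for name in self.spec.population_params:
            v = self.flat(name)
            rows.append(
                {
                    "parameter": name,
                    "mean": float(np.mean(v)),
                    "sd": float(np.std(v, ddof=1)),
                    "q2.5": float(np.percentile(v, 2.5)),
                    "q97.5": float(np.percentile(v, 97.5)),
                    "rhat": self.rhat[name],
                    "ess": self.ess[name],
                }
            )
        return pd.DataFrame(rows).set_index("parameter")


# ---------------------------------------------------------------------------
# fitting


def _make_log_posterior(spec: ModelSpec, data: ModelData):
    J = data.n_participants
    y, x, pid = data.y, data.x, data.pid

    def log_post(theta: np.ndarray) -> np.ndarray:
        t = np.atleast_2d(theta)
        lp = spec.log_prior_unconstrained(t, J)
        ok = np.isfinite(lp)
        ll = np.zeros(t.shape[0])
        if ok.any() and y.size:
            p = spec.unpack(t[ok], J)
            e0, e1 = spec.participant_effects(p)
            mu = spec.mean_function(e0[:, pid], e1[:, pid], x)
            se = p["sigma_e"][:, None]
            resid = (y[None, :] - mu) / se
            ll_ok = np.sum(-0.5 * resid**2 - np.log(se) - 0.5 * _LOG_2PI, axis=1)
            ll[ok] = ll_ok
        out = lp + ll
        out[~np.isfinite(out)] = -np.inf
        return out if np.asarray(theta).ndim == 2 else float(out[0])

    return log_post


def _pointwise_loglik(spec: ModelSpec, data: ModelData, theta_flat: np.ndarray) -> np.ndarray:
    J = data.n_participants
    out = np.empty((theta_flat.shape[0], data.n_obs))
    # chunked to bound memory at ~ (chunk x n_obs) doubles
    chunk = max(1, int(2e6 // max(data.n_obs, 1)))
    for s in range(0, theta_flat.shape[0], chunk):
        t = theta_flat[s : s + chunk]
        p = spec.unpack(t, J)
        e0, e1 = spec.participant_effects(p)
        mu = spec.mean_function(e0[:, data.pid], e1[:, data.pid], data.x)
        se = p["sigma_e"][:, None]
        out[s : s + chunk] = (
            -0.5 * ((data.y[None, :] - mu) / se) ** 2 - np.log(se) - 0.5 * _LOG_2PI
        )
    return out


def fit(
    spec: ModelSpec,
    dataset: RatingDataset | ModelData,
    chains: int = 4,
    warmup: int = 2000,
    total_draws: int = 20000,
    seed: int = 0,
    thin: int = 5,
    rhat_threshold: float = 1.01,
) -> PosteriorSamples:
    """Fit a hierarchical model by ensemble MCMC.

    ``warmup`` ensemble moves are discarded, then moves are thinned by
    ``thin`` until ``total_draws`` post-warmup draws are retained across all
    walkers.  The walker count is the larger of 2*ndim + 2 and 2*chains
    (rounded even).  R-hat is computed per population parameter treating
    walkers as chains; values above ``rhat_threshold`` trigger a
    :class:`ConvergenceWarning` and mark the result as non-converged.
    """
    data = dataset if isinstance(dataset, ModelData) else prepare_model_data(dataset)
    rng = np.random.default_rng(seed)
    ndim = spec.n_dim(data.n_participants)
    nwalkers = max(2 * ndim + 2, 2 * chains)
    nwalkers += nwalkers % 2
    log_post = _make_log_posterior(spec, data)

    theta0 = spec.initial_guess(data, rng)
    p0 = theta0[None, :] + 0.02 * rng.standard_normal((nwalkers, ndim))
    # make sure every walker starts at finite density
    lp0 = log_post(p0)
    bad = ~np.isfinite(lp0)
    for _ in range(50):
        if not bad.any():
            break
        p0[bad] = theta0[None, :] + 0.01 * rng.standard_normal((int(bad.sum()), ndim))
        lp0 = log_post(p0)
        bad = ~np.isfinite(lp0)

    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(
        nwalkers, ndim, log_post, vectorize=True, moves=moves
    )
    sampler._random = np.random.RandomState(int(rng.integers(2**31 - 1)))
    state = sampler.run_mcmc(p0, warmup, skip_initial_state_check=True)
    sampler.reset()
    keep_per_walker = int(np.ceil(total_draws / nwalkers))
    sampler.run_mcmc(state, keep_per_walker * thin, thin_by=thin,
                     skip_initial_state_check=True)
    chain = sampler.get_chain()  # (steps, walkers, ndim)
    theta = np.moveaxis(chain, 0, 1)  # (walkers, steps, ndim)

    J = data.n_participants
    flat = theta.reshape(-1, ndim)
    packed = spec.unpack(flat, J)
    draws = {
        name: packed[name].reshape(theta.shape[0], theta.shape[1])
        for name in spec.population_params
    }

    rhat: dict[str, float] = {}
    ess: dict[str, float] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, arr in draws.items():
            ds = az.convert_to_dataset(arr)
            rhat[name] = float(az.rhat(ds)["x"].values)
            ess[name] = float(az.ess(ds)["x"].values)
    converged = all(np.isfinite(v) and v <= rhat_threshold for v in rhat.values())
    if not converged:
        worst = max(rhat, key=lambda k: rhat[k])
        warnings.warn(
            f"{spec.name} model: R-hat {rhat[worst]:.3f} for {worst!r} exceeds "
            f"{rhat_threshold}; treat posterior with caution",
            ConvergenceWarning,
            stacklevel=2,
        )

    pointwise = _pointwise_loglik(spec, data, flat) if data.n_obs else np.empty((flat.shape[0], 0))
    return PosteriorSamples(
        spec=spec,
        data=data,
        draws=draws,
        theta=theta,
        pointwise_loglik=pointwise,
        log_posterior=log_post,
        rhat=rhat,
        ess=ess,
        converged=converged,
        settings={
            "chains": chains,
            "warmup": warmup,
            "total_draws": total_draws,
            "thin": thin,
            "nwalkers": nwalkers,
            "seed": seed,
        },
    )
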