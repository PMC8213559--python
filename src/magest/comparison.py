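"""Model comparison: bridge-sampling marginal likelihoods, Bayes factors,
WAIC and PSIS-LOO.

The marginal likelihood estimator is the iterative optimal bridge of Meng &
Wong, with a moment-matched multivariate-normal proposal fitted to one half
of the posterior draws on the unconstrained scale (the other half enters the
bridge identity).  Repetitions re-draw the proposal sample while reusing the
posterior draws, and the spread over repetitions quantifies estimator noise.

WAIC follows the standard definition -2 * (lppd - p_waic) with p_waic the
summed posterior variance of the pointwise log densities; LOO uses
Pareto-smoothed importance sampling, degenerating gracefully to WAIC when
the posterior is a point mass.  Standard errors are observation-wise on the
deviance (-2) scale.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import logsumexp

from .models import PosteriorSamples

__all__ = [
    "MarginalLikelihoodEstimate",
    "BayesFactorResult",
    "FitIndices",
    "bridge_logml",
    "bridge_logml_from_draws",
    "log_bayes_factor",
    "waic",
    "loo",
    "fit_indices",
]


@dataclass(frozen=True)
class MarginalLikelihoodEstimate:
    """Repeated bridge-sampling log marginal likelihoods for one model."""

    logml_reps: tuple[float, ...]
    model_label: str = ""
    dataset_label: str = ""

    def __post_init__(self) -> None:
        if len(self.logml_reps) < 1:
            raise ValueError("need at least one repetition")

    @property
    def n_reps(self) -> int:
        return len(self.logml_reps)

    @property
    def mean(self) -> float:
        return float(np.mean(self.logml_reps))

    @property
    def sd(self) -> float:
        return float(np.std(self.logml_reps, ddof=1)) if self.n_reps > 1 else 0.0


@dataclass(frozen=True)
class BayesFactorResult:
    """Per-repetition log Bayes factors (model A vs. model B)."""

    log_bf_reps: tuple[float, ...]
    label_a: str = ""
    label_b: str = ""

    @property
    def mean(self) -> float:
        return float(np.mean(self.log_bf_reps))

    @property
    def sd(self) -> float:
        return float(np.std(self.log_bf_reps, ddof=1)) if len(self.log_bf_reps) > 1 else 0.0


@dataclass(frozen=True)
class FitIndices:
    """WAIC and LOOIC with standard errors and effective parameter counts."""

    waic: float
    waic_se: float
    p_waic: float
    looic: float
    looic_se: float
    p_loo: float
    pareto_k: tuple[float, ...] = field(default=(), repr=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "waic": self.waic,
            "waic_se": self.waic_se,
            "p_waic": self.p_waic,
            "looic": self.looic,
            "looic_se": self.looic_se,
            "p_loo": self.p_loo,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


# ---------------------------------------------------------------------------
# bridge sampling


def _iterate_bridge(l1: np.ndarray, l2: np.ndarray, tol: float, max_iter: int) -> float:
    """Iterative optimal-bridge identity in log space.

    l1: log q - log g on posterior draws; l2: same on proposal draws.
    Returns the log of the normalising-constant ratio log(q/g-normaliser),
    i.e. the log marginal likelihood when q is likelihood x prior.
    """
    n1, n2 = l1.size, l2.size
    ls1, ls2 = np.log(n1 / (n1 + n2)), np.log(n2 / (n1 + n2))
    lstar = float(np.median(l1))
    logr = 0.0
    for _ in range(max_iter):
        num = logsumexp(
            (l2 - lstar) - np.logaddexp(ls1 + (l2 - lstar), ls2 + logr)
        ) - np.log(n2)
        den = logsumexp(
            -np.logaddexp(ls1 + (l1 - lstar), ls2 + logr)
        ) - np.log(n1)
        logr_new = num - den
        if abs(logr_new - logr) < tol * max(1.0, abs(logr_new)):
            return float(logr_new + lstar)
        logr = logr_new
    raise RuntimeError(f"bridge iteration failed to converge in {max_iter} steps")


def bridge_logml_from_draws(
    theta: np.ndarray,
    log_posterior: Callable[[np.ndarray], np.ndarray],
    n_reps: int = 10,
    seed: int = 0,
    tol: float = 1e-10,
    max_iter: int = 1000,
    model_label: str = "",
    dataset_label: str = "",
) -> MarginalLikelihoodEstimate:
    """Bridge-sampling log marginal likelihood from unconstrained draws.

    ``theta`` has shape (S, D); ``log_posterior`` evaluates the unnormalised
    joint density (likelihood x prior, Jacobians included) batch-wise.  The
    first half of the draws fits the multivariate-normal proposal, the second
    half enters the bridge; each repetition re-draws the proposal sample.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.ndim != 2:
        raise ValueError("theta must be (draws, dim)")
    S = theta.shape[0]
    half = S // 2
    fit_part, eval_part = theta[:half], theta[half:]
    mean = fit_part.mean(axis=0)
    cov = np.atleast_2d(np.cov(fit_part, rowvar=False))
    cov += 1e-10 * np.eye(cov.shape[0]) * max(1.0, np.trace(cov))
    chol = np.linalg.cholesky(cov)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    D = cov.shape[0]

    def mvn_logpdf(z: np.ndarray) -> np.ndarray:
        r = solve_triangular(chol, (z - mean).T, lower=True).T
        return -0.5 * np.sum(r**2, axis=1) - 0.5 * (D * np.log(2 * np.pi) + logdet)

    lq_eval = np.asarray(log_posterior(eval_part), dtype=float)
    if not np.all(np.isfinite(lq_eval)):
        raise ValueError("non-finite posterior density on posterior draws")
    l1 = lq_eval - mvn_logpdf(eval_part)

    rng = np.random.default_rng(seed)
    reps = []
    n2 = eval_part.shape[0]
    for _ in range(n_reps):
        z = rng.standard_normal((n2, D))
        prop = mean + z @ chol.T
        lq_prop = np.asarray(log_posterior(prop), dtype=float)
        lg_prop = -0.5 * np.sum(z**2, axis=1) - 0.5 * (D * np.log(2 * np.pi) + logdet)
        finite = np.isfinite(lq_prop)
        l2 = np.where(finite, lq_prop, -np.inf) - lg_prop
        reps.append(_iterate_bridge(l1, l2, tol, max_iter))
    return MarginalLikelihoodEstimate(
        tuple(reps), model_label=model_label, dataset_label=dataset_label
    )


def bridge_logml(
    samples: PosteriorSamples,
    n_reps: int = 10,
    seed: int = 0,
    tol: float = 1e-10,
    max_iter: int = 1000,
    dataset_label: str = "",
) -> MarginalLikelihoodEstimate:
    """Bridge-sampling marginal likelihood of a fitted hierarchical model."""
    return bridge_logml_from_draws(
        samples.flat_theta(),
        samples.log_posterior,
        n_reps=n_reps,
        seed=seed,
        tol=tol,
        max_iter=max_iter,
        model_label=samples.spec.name,
        dataset_label=dataset_label,
    )


def log_bayes_factor(
    ml_a: MarginalLikelihoodEstimate, ml_b: MarginalLikelihoodEstimate
) -> BayesFactorResult:
    """Pairwise log Bayes factors from two repeated logml estimates.

    Antisymmetric: swapping the arguments negates every repetition.
    """
    if ml_a.dataset_label != ml_b.dataset_label:
        raise ValueError(
            f"marginal likelihoods from different datasets: "
            f"{ml_a.dataset_label!r} vs {ml_b.dataset_label!r}"
        )
    n = min(ml_a.n_reps, ml_b.n_reps)
    diffs = tuple(
        float(a - b) for a, b in zip(ml_a.logml_reps[:n], ml_b.logml_reps[:n])
    )
    return BayesFactorResult(diffs, label_a=ml_a.model_label, label_b=ml_b.model_label)


# ---------------------------------------------------------------------------
# information criteria


def _check_ll(pointwise_loglik: np.ndarray) -> np.ndarray:
    ll = np.asarray(pointwise_loglik, dtype=float)
    if ll.ndim != 2:
        raise ValueError("pointwise log-likelihood must be (draws, observations)")
    if not np.all(np.isfinite(ll)):
        raise ValueError("non-finite pointwise log-likelihood entries")
    return ll


def waic(pointwise_loglik: np.ndarray) -> tuple[float, float, float]:
    """WAIC on the deviance scale: (waic, se, p_waic).

    waic = -2 * sum_i (lppd_i - p_i), p_i the posterior variance of the
    pointwise log density; se is sqrt(n * var) of the observation-wise
    contributions.  A single draw gives p_waic = 0 and waic =
    -2 * sum log density.
    """
    ll = _check_ll(pointwise_loglik)
    S, n = ll.shape
    lppd_i = logsumexp(ll, axis=0) - np.log(S)
    p_i = ll.var(axis=0, ddof=1) if S > 1 else np.zeros(n)
    elpd_i = lppd_i - p_i
    waic_i = -2.0 * elpd_i
    se = float(np.sqrt(n * np.var(waic_i, ddof=1))) if n > 1 else 0.0
    return float(np.sum(waic_i)), se, float(np.sum(p_i))


def loo(pointwise_loglik: np.ndarray) -> tuple[float, float, float, np.ndarray]:
    """PSIS-LOO on the deviance scale: (looic, se, p_loo, pareto_k).

    Importance weights 1/p(y_i | theta) are Pareto-smoothed per observation;
    shape diagnostics are returned but never used to refuse a result.  With a
    degenerate (point) posterior the weights are uniform and LOOIC equals
    WAIC exactly.
    """
    ll = _check_ll(pointwise_loglik)
    S, n = ll.shape
    lppd_i = logsumexp(ll, axis=0) - np.log(S)
    if S == 1 or np.allclose(ll.var(axis=0), 0.0):
        elpd_i = lppd_i
        k = np.zeros(n)
    else:
        import arviz as az

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lw, k = az.psislw(-ll.T)  # (n, S) log weights, normalised per row
        lw = np.asarray(lw)
        k = np.asarray(k, dtype=float)
        elpd_i = logsumexp(ll.T + lw, axis=1)
    loo_i = -2.0 * elpd_i
    se = float(np.sqrt(n * np.var(loo_i, ddof=1))) if n > 1 else 0.0
    p_loo = float(np.sum(lppd_i - elpd_i))
    return float(np.sum(loo_i)), se, p_loo, k


def fit_indices(pointwise_loglik: np.ndarray) -> FitIndices:
    """WAIC and PSIS-LOO bundled for reporting."""
    w, w_se, p_w = waic(pointwise_loglik)
    l, l_se, p_l, k = loo(pointwise_loglik)
    return FitIndices(
        waic=w,
        waic_se=w_se,
        p_waic=p_w,
        looic=l,
        looic_se=l_se,
        p_loo=p_l,
        pareto_k=tuple(float(v) for v in k),
    )
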