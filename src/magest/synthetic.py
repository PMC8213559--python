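"""Synthetic magnitude-estimation experiments.

Simulated observers carry individual power-law response functions
psi(I) = k * I^a (k > 0 proportionality constant, a > 0 exponent) with
between-subject variation in both parameters.  On each trial the latent
perceived ratio of test to reference, f = psi(I_test) / psi(I_ref), is mapped
to a numeric rating through one of the response formats used in the
experiments:

* ``standard``       — rating 10*f (modulus 10 at the reference);
* ``reversal``       — rating 10/f (response scale inverted);
* ``unidirectional`` — binary direction judgment, then rating 10*max(f, 1/f)
  (always at or above the modulus);
* ``binary_standard``— a direction judgment followed by a standard-format
  rating (control condition; direction errors injectable).

Gaussian response noise is added on the normalised (rating/100) scale — the
same scale on which the hierarchical models define their likelihood — and the
result is mapped back to rating units, truncated at the format's lower bound.

Each study's design is available as a preset: 8 test stimuli, 5 repetitions
(40 trials per condition), sample sizes and population parameters matching the
luminance and red-saturation experiments.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .stimuli import StimulusSet, luminance_stimulus_table, red_stimulus_table

__all__ = [
    "PsychometricFunction",
    "PopulationSpec",
    "RatingDataset",
    "METHODS",
    "draw_participants",
    "simulate_ratings",
    "apply_anchoring_bias",
    "study_population",
    "study_stimuli",
]

METHODS = ("standard", "reversal", "unidirectional", "binary_standard")
_DIRECTED = ("unidirectional", "binary_standard")

#: exact column order of the trial-level CSV schema
CSV_COLUMNS = [
    "participant_id",
    "method",
    "stimulus_id",
    "intensity",
    "response",
    "direction",
    "trial_index",
]


@dataclass(frozen=True)
class PsychometricFunction:
    """psi(I) = k * I^a, strictly increasing for k, a > 0."""

    k: float
    a: float

    def __post_init__(self) -> None:
        if self.k <= 0 or self.a <= 0:
            raise ValueError("k and a must be positive")

    def __call__(self, intensity: float | np.ndarray) -> float | np.ndarray:
        return self.k * np.asarray(intensity, dtype=float) ** self.a

    def perceived_ratio(self, intensity, reference_intensity):
        """f = psi(I) / psi(I_ref); k cancels."""
        return (np.asarray(intensity, dtype=float) / reference_intensity) ** self.a


@dataclass(frozen=True)
class PopulationSpec:
    """Population of simulated observers and the trial structure.

    k and a are drawn from normal distributions truncated at zero.
    ``noise_sd`` is the residual SD on the normalised (rating/100) response
    scale.  ``bias_lambda`` is the mixing weight of the anchoring-bias
    transform (1 = unbiased ratio responder, 0 = pure difference-thinker);
    ``bias_c`` scales the difference response.  ``direction_error_rate``
    injects wrong binary direction judgments (directed formats only).
    """

    mean_k: float = 1.0
    sd_k: float = 0.2
    mean_a: float = 0.5
    sd_a: float = 0.15
    noise_sd: float = 0.03
    n_participants: int = 16
    n_reps: int = 5
    bias_lambda: float = 1.0
    bias_c: float = 1.0
    direction_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.sd_k, self.sd_a, self.noise_sd) < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.n_reps < 1 or self.n_participants < 1:
            raise ValueError("counts must be at least 1")
        if not 0.0 <= self.bias_lambda <= 1.0:
            raise ValueError("bias_lambda must lie in [0, 1]")
        if not 0.0 <= self.direction_error_rate <= 1.0:
            raise ValueError("direction_error_rate must lie in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationSpec":
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PopulationSpec":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class RatingDataset:
    """Long-format trial table plus the stimulus set it refers to.

    ``trials`` columns follow the CSV schema (participant_id, method,
    stimulus_id, intensity, response, direction, trial_index); simulator
    output additionally carries a ``latent_f`` column (noiseless perceived
    ratio) which is dropped on CSV export.
    """

    trials: pd.DataFrame
    stimulus_set: StimulusSet
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        known = {sid for sid, _ in self.stimulus_set.stimuli}
        used = set(self.trials["stimulus_id"].unique())
        if not used <= known:
            raise ValueError(f"unknown stimulus ids {used - known}")
        if self.stimulus_set.reference_id in used:
            raise ValueError("reference stimulus must not appear as a test stimulus")
        bad = set(self.trials["method"].unique()) - set(METHODS)
        if bad:
            raise ValueError(f"unknown methods {bad}")

    def copy_with(self, trials: pd.DataFrame) -> "RatingDataset":
        return RatingDataset(trials, self.stimulus_set, dict(self.provenance))

    def to_csv(self, path: str | Path | io.TextIOBase) -> None:
        out = self.trials[CSV_COLUMNS].copy()
        out["direction"] = out["direction"].fillna("")
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, stimulus_set: StimulusSet) -> "RatingDataset":
        df = pd.read_csv(path, keep_default_na=False, na_values=[])
        if list(df.columns) != CSV_COLUMNS:
            raise ValueError(f"unexpected columns {list(df.columns)!r}")
        df["direction"] = df["direction"].mask(df["direction"] == "", np.nan)
        df["response"] = df["response"].astype(float)
        df["intensity"] = df["intensity"].astype(float)
        return cls(df, stimulus_set, {"source": str(path)})


def draw_participants(pop: PopulationSpec) -> list[PsychometricFunction]:
    """Draw n_participants (k, a) pairs from zero-truncated normals.

    Deterministic given ``pop.seed``; degenerate spread (sd = 0) returns the
    population means exactly.
    """
    rng = np.random.default_rng(pop.seed)

    def _draw(mean: float, sd: float) -> np.ndarray:
        if sd == 0:
            return np.full(pop.n_participants, mean)
        lo = (0.0 - mean) / sd
        u = rng.random(pop.n_participants)
        return stats.truncnorm.ppf(u, lo, np.inf, loc=mean, scale=sd)

    ks = _draw(pop.mean_k, pop.sd_k)
    aa = _draw(pop.mean_a, pop.sd_a)
    return [PsychometricFunction(k=float(k), a=float(a)) for k, a in zip(ks, aa)]


def _format_rating(f: np.ndarray, method: str) -> tuple[np.ndarray, np.ndarray | None]:
    """Noiseless rating and direction labels for one response format."""
    if method in ("standard", "binary_standard"):
        rating = 10.0 * f
    elif method == "reversal":
        rating = 10.0 / f
    elif method == "unidirectional":
        rating = 10.0 * np.maximum(f, 1.0 / f)
    else:
        raise ValueError(f"unknown method {method!r}")
    direction = None
    if method in _DIRECTED:
        direction = np.where(f > 1.0, "higher", "lower")
    return rating, direction


def simulate_ratings(
    participants: list[PsychometricFunction],
    stimulus_set: StimulusSet,
    method: str,
    pop: PopulationSpec,
) -> RatingDataset:
    """Simulate 8 test stimuli x n_reps trials per participant for one format.

    Noise is N(0, noise_sd) on the normalised rating/100 scale, added to the
    noiseless format rating and truncated at the format's lower bound (0 for
    standard/reversal/binary_standard, the modulus 10 for unidirectional,
    whose response scale does not extend below the reference value).
    Direction judgments come from the noiseless latent ratio; with
    ``direction_error_rate`` > 0 a matching fraction is flipped
    (binary_standard and unidirectional).
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng((pop.seed, METHODS.index(method)))
    xmap = stimulus_set.normalized()
    x_ref = xmap[stimulus_set.reference_id]
    test_ids = np.array(stimulus_set.test_ids)
    x_test = np.array([xmap[s] for s in test_ids])

    rows = []
    for j, fn in enumerate(participants):
        f_stim = fn.perceived_ratio(x_test, x_ref)  # (8,)
        f = np.repeat(f_stim, pop.n_reps)
        sids = np.repeat(test_ids, pop.n_reps)
        rating0, direction = _format_rating(f, method)
        noise = rng.normal(0.0, pop.noise_sd, size=f.size) if pop.noise_sd > 0 else 0.0
        floor = 10.0 if method == "unidirectional" else 0.0
        rating = np.maximum(floor, rating0 + 100.0 * noise)
        if direction is not None and pop.direction_error_rate > 0:
            flip = rng.random(f.size) < pop.direction_error_rate
            direction = np.where(
                flip, np.where(direction == "higher", "lower", "higher"), direction
            )
        order = rng.permutation(f.size)
        for t, idx in enumerate(order):
            rows.append(
                (
                    j,
                    method,
                    int(sids[idx]),
                    stimulus_set.intensity(int(sids[idx])),
                    float(rating[idx]),
                    direction[idx] if direction is not None else np.nan,
                    t,
                    float(f[idx]),
                )
            )
    df = pd.DataFrame(rows, columns=CSV_COLUMNS + ["latent_f"])
    return RatingDataset(df, stimulus_set, {"population": pop.to_dict(), "method": method})


def apply_anchoring_bias(
    dataset: RatingDataset, bias_lambda: float, bias_c: float = 1.0
) -> RatingDataset:
    """Blend standard-format below-reference ratings towards difference-thinking.

    For trials whose latent perceived ratio f is below 1 the rating becomes
    lambda * r + (1 - lambda) * max(0, 10 - c*(1/f - 1)): a responder who
    reports the perceived *difference* to the reference on the 0-10 sub-scale
    instead of the required ratio.  lambda = 1 is the identity;
    above-reference trials are never touched.  Requires simulator-origin data
    (the latent ratio column).
    """
    if not 0.0 <= bias_lambda <= 1.0:
        raise ValueError("bias_lambda must lie in [0, 1]")
    methods = set(dataset.trials["method"].unique())
    if not methods <= {"standard", "binary_standard"}:
        raise ValueError("anchoring bias applies to standard-format datasets only")
    if "latent_f" not in dataset.trials.columns:
        raise ValueError("dataset lacks latent ratios (not simulator output)")
    df = dataset.trials.copy()
    f = df["latent_f"].to_numpy(dtype=float)
    below = f < 1.0
    diff_response = np.maximum(0.0, 10.0 - bias_c * (1.0 / f[below] - 1.0))
    df.loc[below, "response"] = (
        bias_lambda * df.loc[below, "response"].to_numpy() + (1.0 - bias_lambda) * diff_response
    )
    out = dataset.copy_with(df)
    out.provenance["bias_lambda"] = bias_lambda
    out.provenance["bias_c"] = bias_c
    return out


def simulate_from_linear_model(
    stimulus_set: StimulusSet,
    beta0: float = 0.05,
    beta1: float = 0.25,
    sd_beta0: float = 0.015,
    sd_beta1: float = 0.10,
    rho: float = 0.0,
    noise_sd: float = 0.04,
    n_participants: int = 16,
    n_reps: int = 5,
    seed: int = 0,
) -> RatingDataset:
    """Reference datasets drawn from the hierarchical *linear* model itself.

    Participant (intercept, slope) pairs are bivariate normal around
    (beta0, beta1); responses are beta0j + beta1j*x + N(0, noise_sd) on the
    normalised scale, mapped to ratings (x100, truncated at 0) under the
    standard format.  Used to calibrate model selection: data generated here
    should favour the linear model over the power law.
    """
    rng = np.random.default_rng(seed)
    cov = np.array(
        [
            [sd_beta0**2, rho * sd_beta0 * sd_beta1],
            [rho * sd_beta0 * sd_beta1, sd_beta1**2],
        ]
    )
    effects = rng.multivariate_normal([beta0, beta1], cov, size=n_participants)
    xmap = stimulus_set.normalized()
    test_ids = np.array(stimulus_set.test_ids)
    x_test = np.array([xmap[s] for s in test_ids])
    rows = []
    for j, (b0j, b1j) in enumerate(effects):
        mu = np.repeat(b0j + b1j * x_test, n_reps)
        sids = np.repeat(test_ids, n_reps)
        y = mu + rng.normal(0.0, noise_sd, size=mu.size)
        rating = np.maximum(0.0, 100.0 * y)
        order = rng.permutation(mu.size)
        for t, idx in enumerate(order):
            rows.append(
                (
                    j,
                    "standard",
                    int(sids[idx]),
                    stimulus_set.intensity(int(sids[idx])),
                    float(rating[idx]),
                    np.nan,
                    t,
                    np.nan,
                )
            )
    df = pd.DataFrame(rows, columns=CSV_COLUMNS + ["latent_f"])
    return RatingDataset(
        df,
        stimulus_set,
        {"generator": "linear_model", "beta0": beta0, "beta1": beta1, "seed": seed},
    )


# ---------------------------------------------------------------------------
# Study presets: designs and population parameters of the three experiments.
# Exponent means/SDs and residual SDs follow the fitted per-condition values
# for the luminance and red-saturation conditions; k is scale-free for ratio
# responses and defaults to 1 +/- 0.2.

_STUDY_DESIGNS: dict[int, dict] = {
    1: {
        "dimension": "luminance",
        "between": False,
        "arms": {
            "standard": dict(mean_a=0.44, sd_a=0.18, noise_sd=0.03, n_participants=20),
            "reversal": dict(mean_a=0.44, sd_a=0.18, noise_sd=0.03, n_participants=20),
        },
    },
    2: {
        "dimension": "luminance",
        "between": True,
        "arms": {
            "standard": dict(mean_a=0.44, sd_a=0.18, noise_sd=0.03, n_participants=16),
            "unidirectional": dict(mean_a=0.55, sd_a=0.30, noise_sd=0.05, n_participants=18),
        },
    },
    3: {
        "dimension": "red_saturation",
        "between": True,
        "arms": {
            "standard": dict(mean_a=1.99, sd_a=1.01, noise_sd=0.04, n_participants=18),
            "unidirectional": dict(mean_a=1.73, sd_a=0.91, noise_sd=0.04, n_participants=18),
        },
    },
}


def study_stimuli(study: int) -> StimulusSet:
    """Stimulus set of a study (1/2: luminance, 3: red saturation)."""
    if study not in _STUDY_DESIGNS:
        raise ValueError(f"unknown study {study!r}")
    if _STUDY_DESIGNS[study]["dimension"] == "luminance":
        return luminance_stimulus_table()
    return red_stimulus_table()


def study_population(study: int, method: str, seed: int = 0) -> PopulationSpec:
    """Population preset for one arm of one study (5 reps, study sample size)."""
    if study not in _STUDY_DESIGNS:
        raise ValueError(f"unknown study {study!r}")
    arms = _STUDY_DESIGNS[study]["arms"]
    if method not in arms:
        raise ValueError(f"study {study} has no {method!r} arm (has {sorted(arms)})")
    return PopulationSpec(seed=seed, n_reps=5, **arms[method])
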