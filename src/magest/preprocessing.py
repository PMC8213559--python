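"""Trial-level transformations applied before analysis.

Fixed pipeline order: floor zero responses (to 0.001, so the reciprocal
recode and the log transform are defined), drop erroneous direction
judgments, bring every response format onto the standard scale via the
reciprocal recode r' = 10/r * 10 = 100/r, then take natural logs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .stimuli import StimulusSet
from .synthetic import RatingDataset

__all__ = [
    "PreprocessReport",
    "recode_reciprocal",
    "floor_zeros",
    "flag_erroneous_direction",
    "to_standard_scale",
    "log_responses",
    "geometric_mean_rating",
    "preprocess",
]

DEFAULT_FLOOR = 0.001


@dataclass
class PreprocessReport:
    """Bookkeeping for one preprocessing stage."""

    n_trials_in: int
    n_trials_out: int
    n_zero_recoded: int = 0
    fraction_zero_recoded: float = 0.0
    n_erroneous_excluded: int = 0
    fraction_erroneous_excluded: float = 0.0
    floor_value: float = DEFAULT_FLOOR

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction_zero_recoded <= 1.0):
            raise ValueError("fraction out of range")
        if not (0.0 <= self.fraction_erroneous_excluded <= 1.0):
            raise ValueError("fraction out of range")
        if self.n_trials_out != self.n_trials_in - self.n_erroneous_excluded:
            raise ValueError("trial counts inconsistent with exclusions")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def recode_reciprocal(r):
    """r' = 10/r * 10 = 100/r — maps reversed/unidirectional ratings onto the
    standard scale (e.g. 20 -> 5).  Involution: applying it twice is the
    identity.  Zeros must be floored first."""
    arr = np.asarray(r, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("reciprocal recode requires strictly positive ratings")
    out = 100.0 / arr
    return float(out) if np.isscalar(r) else out


def floor_zeros(
    dataset: RatingDataset, floor: float = DEFAULT_FLOOR
) -> tuple[RatingDataset, PreprocessReport]:
    """Replace exact-zero responses by ``floor`` (default 0.001)."""
    resp = dataset.trials["response"].to_numpy(dtype=float)
    if np.any(resp < 0):
        raise ValueError("negative responses are invalid")
    zero = resp == 0.0
    df = dataset.trials.copy()
    df.loc[zero, "response"] = floor
    n = len(df)
    report = PreprocessReport(
        n_trials_in=n,
        n_trials_out=n,
        n_zero_recoded=int(zero.sum()),
        fraction_zero_recoded=float(zero.sum()) / n if n else 0.0,
        floor_value=floor,
    )
    return dataset.copy_with(df), report


def flag_erroneous_direction(
    dataset: RatingDataset, stimulus_set: StimulusSet | None = None
) -> tuple[RatingDataset, PreprocessReport]:
    """Drop directed-format trials whose binary judgment contradicts physics.

    A trial is erroneous iff its direction disagrees with the objective
    relation of the test stimulus' intensity to the reference intensity
    ("higher" on a below-reference stimulus or vice versa).  Non-directed
    formats pass through untouched.
    """
    ss = stimulus_set or dataset.stimulus_set
    df = dataset.trials
    directed = df["method"].isin(["unidirectional", "binary_standard"])
    if directed.any() and df.loc[directed, "direction"].isna().any():
        raise ValueError("direction missing on a method that requires it")
    ref = ss.reference_intensity
    above = df["stimulus_id"].map(dict(ss.stimuli)) > ref
    erroneous = directed & (
        (above & (df["direction"] == "lower")) | (~above & (df["direction"] == "higher"))
    )
    n_in = len(df)
    out = df.loc[~erroneous].reset_index(drop=True)
    report = PreprocessReport(
        n_trials_in=n_in,
        n_trials_out=len(out),
        n_erroneous_excluded=int(erroneous.sum()),
        fraction_erroneous_excluded=float(erroneous.sum()) / n_in if n_in else 0.0,
    )
    return dataset.copy_with(out), report


def to_standard_scale(
    dataset: RatingDataset, stimulus_set: StimulusSet | None = None
) -> RatingDataset:
    """Recode every response format onto the standard magnitude scale.

    reversal: reciprocal recode on all trials; unidirectional: reciprocal
    recode on below-reference trials only (those rated on the "how much
    lower" branch); standard and binary_standard: unchanged.
    """
    ss = stimulus_set or dataset.stimulus_set
    df = dataset.trials.copy()
    ref = ss.reference_intensity
    below = df["stimulus_id"].map(dict(ss.stimuli)) < ref
    sel_rev = df["method"] == "reversal"
    sel_uni = (df["method"] == "unidirectional") & below
    sel = sel_rev | sel_uni
    if sel.any():
        df.loc[sel, "response"] = recode_reciprocal(df.loc[sel, "response"].to_numpy())
    return dataset.copy_with(df)


def log_responses(dataset: RatingDataset) -> RatingDataset:
    """Natural-log transform of all responses (must be strictly positive)."""
    resp = dataset.trials["response"].to_numpy(dtype=float)
    if np.any(resp <= 0):
        raise ValueError("log transform requires positive responses; floor zeros first")
    df = dataset.trials.copy()
    df["response"] = np.log(resp)
    return dataset.copy_with(df)


def geometric_mean_rating(dataset: RatingDataset, stimulus_id: int) -> float:
    """Mean rating calculated from the mean log rating, exp(mean(ln r))."""
    r = dataset.trials.loc[
        dataset.trials["stimulus_id"] == stimulus_id, "response"
    ].to_numpy(dtype=float)
    if r.size == 0:
        raise ValueError(f"no trials for stimulus {stimulus_id}")
    if np.any(r <= 0):
        raise ValueError("geometric mean requires positive ratings")
    return float(np.exp(np.mean(np.log(r))))


def preprocess(
    dataset: RatingDataset,
    floor: float = DEFAULT_FLOOR,
    log: bool = False,
) -> tuple[RatingDataset, PreprocessReport]:
    """Full pipeline: floor zeros -> drop erroneous directions -> standard
    scale -> (optionally) natural log.  Returns the combined report."""
    ds, rep_floor = floor_zeros(dataset, floor=floor)
    ds, rep_err = flag_erroneous_direction(ds)
    ds = to_standard_scale(ds)
    if log:
        ds = log_responses(ds)
    report = PreprocessReport(
        n_trials_in=rep_floor.n_trials_in,
        n_trials_out=rep_err.n_trials_out,
        n_zero_recoded=rep_floor.n_zero_recoded,
        fraction_zero_recoded=rep_floor.fraction_zero_recoded,
        n_erroneous_excluded=rep_err.n_erroneous_excluded,
        fraction_erroneous_excluded=rep_err.fraction_erroneous_excluded,
        floor_value=floor,
    )
    return ds, report
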