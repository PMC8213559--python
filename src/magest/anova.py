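"""Repeated-measures and mixed ANOVA on log ratings.

The experiments are 2 (method) x 8 (stimulus) designs: fully within-subject
(both methods done by everyone) or mixed (method between subjects).  The
analysis operates on cell means — one mean log response per participant x
method x stimulus, averaging the 5 repetitions — and reports F statistics
with Greenhouse-Geisser-corrected degrees of freedom and p values for every
within-subject effect, plus generalized eta squared.

Greenhouse-Geisser epsilon is Box's estimate computed per effect from the
covariance of the within-subject contrast scores (the convention of car/afex
in R); generalized eta squared follows the Olejnik-Algina/Bakeman definition
SS_effect / (SS_effect + sum of all subject-level error SS).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import RatingDataset

__all__ = ["EffectResult", "AnovaResult", "cell_means", "gg_epsilon", "mixed_anova"]


@dataclass(frozen=True)
class EffectResult:
    """One ANOVA effect: F, df, GG correction, p values, effect size, SS."""

    name: str
    ss: float
    ss_error: float
    df1: float
    df2: float
    F: float
    epsilon: float
    df1_corr: float
    df2_corr: float
    p_uncorrected: float
    p_gg: float
    eta_g_sq: float


@dataclass(frozen=True)
class AnovaResult:
    design: str  # "within" | "mixed"
    effects: tuple[EffectResult, ...]

    def __getitem__(self, name: str) -> EffectResult:
        for e in self.effects:
            if e.name == name:
                return e
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(e) for e in self.effects]).set_index("name")

    def to_json(self, path: str | Path) -> None:
        payload = {"design": self.design, "effects": [asdict(e) for e in self.effects]}
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    def report(self) -> str:
        """Human-readable lines in the field's F(df1, df2) reporting style."""
        lines = []
        for e in self.effects:
            lines.append(
                f"{e.name}: F({e.df1_corr:.2f}, {e.df2_corr:.2f}) = {e.F:.2f}, "
                f"p = {e.p_gg:.4g}, eta_g^2 = {e.eta_g_sq:.3f}"
            )
        return "\n".join(lines)


def cell_means(dataset: RatingDataset) -> pd.DataFrame:
    """Mean response per participant x method x stimulus cell (long format).

    Every participant/method combination must contribute all of its stimuli
    with at least one repetition each; missing cells raise.
    """
    df = dataset.trials
    cells = (
        df.groupby(["participant_id", "method", "stimulus_id"], sort=True)["response"]
        .mean()
        .reset_index()
    )
    counts = cells.groupby(["participant_id", "method"])["stimulus_id"].count()
    if counts.nunique() > 1:
        raise ValueError("missing cells: unequal stimulus counts across participants")
    return cells


def gg_epsilon(within_cell_covariance: np.ndarray) -> float:
    """Box's epsilon estimate for an L-level within factor.

    (tr S_c)^2 / ((L-1) tr(S_c^2)) with S_c the double-centered covariance;
    equals 1 under sphericity (e.g. compound symmetry) and exactly 1 for
    L = 2; bounded below by 1/(L-1).
    """
    S = np.asarray(within_cell_covariance, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("covariance must be square")
    if not np.allclose(S, S.T, atol=1e-8):
        raise ValueError("covariance must be symmetric")
    L = S.shape[0]
    if L < 2:
        raise ValueError("need at least two levels")
    w = np.linalg.eigvalsh((S + S.T) / 2.0)
    if w.min() < -1e-8 * max(1.0, w.max()):
        raise ValueError("covariance must be positive semi-definite")
    H = np.eye(L) - np.ones((L, L)) / L
    Sc = H @ S @ H
    num = np.trace(Sc) ** 2
    den = (L - 1) * np.trace(Sc @ Sc)
    if den == 0:
        return 1.0
    return float(min(1.0, num / den))


def _contrast_epsilon(cov: np.ndarray, C: np.ndarray) -> float:
    """Box epsilon of the effect-specific contrast covariance C cov C'."""
    M = C @ cov @ C.T
    d = M.shape[0]
    if d == 1:
        return 1.0
    lam = np.linalg.eigvalsh((M + M.T) / 2.0)
    den = d * np.sum(lam**2)
    if den == 0:
        return 1.0
    return float(min(1.0, np.sum(lam) ** 2 / den))


def _orthonormal_contrasts(L: int) -> np.ndarray:
    """(L-1) x L orthonormal rows spanning the centered space."""
    H = np.eye(L) - np.ones((L, L)) / L
    w, v = np.linalg.eigh(H)
    return v[:, w > 0.5].T


def _effect(name, ss, ss_err, df1, df2, eps, ss_error_total) -> EffectResult:
    F = (ss / df1) / (ss_err / df2)
    return EffectResult(
        name=name,
        ss=float(ss),
        ss_error=float(ss_err),
        df1=float(df1),
        df2=float(df2),
        F=float(F),
        epsilon=float(eps),
        df1_corr=float(eps * df1),
        df2_corr=float(eps * df2),
        p_uncorrected=float(stats.f.sf(F, df1, df2)),
        p_gg=float(stats.f.sf(F, eps * df1, eps * df2)),
        eta_g_sq=float(ss / (ss + ss_error_total)),
    )


def _within_anova(wide: np.ndarray, n_m: int, n_l: int) -> AnovaResult:
    """Fully within two-factor ANOVA; wide is (subjects, n_m*n_l), cells
    ordered method-major (m varies slowest)."""
    n = wide.shape[0]
    Y = wide.reshape(n, n_m, n_l)
    grand = Y.mean()
    subj = Y.mean(axis=(1, 2))
    A = Y.mean(axis=(0, 2))  # method means
    B = Y.mean(axis=(0, 1))  # stimulus means
    AB = Y.mean(axis=0)  # method x stimulus cell means
    ss_subj = n_m * n_l * np.sum((subj - grand) ** 2)
    ss_A = n * n_l * np.sum((A - grand) ** 2)
    ss_B = n * n_m * np.sum((B - grand) ** 2)
    ss_AB = n * np.sum((AB - A[:, None] - B[None, :] + grand) ** 2)
    iA = Y.mean(axis=2)  # subject x method
    iB = Y.mean(axis=1)  # subject x stimulus
    ss_AxS = n_l * np.sum((iA - subj[:, None] - A[None, :] + grand) ** 2)
    ss_BxS = n_m * np.sum((iB - subj[:, None] - B[None, :] + grand) ** 2)
    ss_T = np.sum((Y - grand) ** 2)
    ss_ABS = ss_T - ss_subj - ss_A - ss_B - ss_AB - ss_AxS - ss_BxS

    cov = np.cov(wide, rowvar=False)
    QM = _orthonormal_contrasts(n_m)
    QL = _orthonormal_contrasts(n_l)
    oneM = np.full((1, n_m), 1.0 / n_m)
    oneL = np.full((1, n_l), 1.0 / n_l)
    eps_A = _contrast_epsilon(cov, np.kron(QM, oneL))
    eps_B = _contrast_epsilon(cov, np.kron(oneM, QL))
    eps_AB = _contrast_epsilon(cov, np.kron(QM, QL))

    err_total = ss_subj + ss_AxS + ss_BxS + ss_ABS
    effects = (
        _effect("method", ss_A, ss_AxS, n_m - 1, (n - 1) * (n_m - 1), eps_A, err_total),
        _effect("stimulus", ss_B, ss_BxS, n_l - 1, (n - 1) * (n_l - 1), eps_B, err_total),
        _effect(
            "method:stimulus",
            ss_AB,
            ss_ABS,
            (n_m - 1) * (n_l - 1),
            (n - 1) * (n_m - 1) * (n_l - 1),
            eps_AB,
            err_total,
        ),
    )
    return AnovaResult(design="within", effects=effects)


def _mixed_anova(groups: list[np.ndarray]) -> AnovaResult:
    """Mixed ANOVA: between factor = group, within = columns.  Each array is
    (n_g, L).  Proportional cell frequencies keep the sequential SS
    orthogonal, so unequal group sizes are allowed."""
    G = len(groups)
    L = groups[0].shape[1]
    ns = np.array([g.shape[0] for g in groups])
    N = int(ns.sum())
    all_Y = np.vstack(groups)
    grand = all_Y.mean()
    subj = all_Y.mean(axis=1)
    ss_bs = L * np.sum((subj - grand) ** 2)
    gmeans = np.array([g.mean() for g in groups])
    ss_A = L * np.sum(ns * (gmeans - grand) ** 2)
    ss_SwG = ss_bs - ss_A
    lmeans = all_Y.mean(axis=0)
    ss_B = N * np.sum((lmeans - grand) ** 2)
    ss_AB = 0.0
    for g, (arr, gm) in enumerate(zip(groups, gmeans)):
        cl = arr.mean(axis=0)
        ss_AB += ns[g] * np.sum((cl - gm - lmeans + grand) ** 2)
    ss_T = np.sum((all_Y - grand) ** 2)
    ss_err_w = ss_T - ss_bs - ss_B - ss_AB

    # pooled within-group covariance drives the GG correction
    pooled = sum((arr.shape[0] - 1) * np.cov(arr, rowvar=False) for arr in groups) / (N - G)
    eps = gg_epsilon(pooled)

    err_total = ss_SwG + ss_err_w
    effects = (
        _effect("method", ss_A, ss_SwG, G - 1, N - G, 1.0, err_total),
        _effect("stimulus", ss_B, ss_err_w, L - 1, (N - G) * (L - 1), eps, err_total),
        _effect(
            "method:stimulus", ss_AB, ss_err_w, (G - 1) * (L - 1), (N - G) * (L - 1), eps, err_total
        ),
    )
    return AnovaResult(design="mixed", effects=effects)


def mixed_anova(
    dataset: RatingDataset,
    within: str = "stimulus_id",
    between: str | None = None,
) -> AnovaResult:
    """2 x 8 ANOVA on cell means of (log) responses.

    ``between=None`` treats method as a within-subject factor (everyone did
    both formats); ``between="method"`` runs the mixed design with method as
    a between-subjects factor.  Requires complete cells and at least two
    participants per group.
    """
    cells = cell_means(dataset)
    methods = sorted(cells["method"].unique())
    if between is None:
        if len(methods) < 2:
            raise ValueError("within design needs every participant in both methods")
        wide = cells.pivot_table(
            index="participant_id", columns=["method", within], values="response"
        )
        if wide.isna().any().any():
            raise ValueError("missing cells")
        if len(wide) < 2:
            raise ValueError("need at least two participants")
        n_l = cells[within].nunique()
        return _within_anova(wide.to_numpy(), len(methods), n_l)
    if between != "method":
        raise ValueError("the between factor must be 'method'")
    groups = []
    for m in methods:
        sub = cells[cells["method"] == m]
        wide = sub.pivot_table(index="participant_id", columns=within, values="response")
        if wide.isna().any().any():
            raise ValueError(f"missing cells in group {m!r}")
        if len(wide) < 2:
            raise ValueError("need at least two participants per group")
        groups.append(wide.to_numpy())
    if len(groups) < 2:
        raise ValueError("mixed design needs at least two method groups")
    return _mixed_anova(groups)
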