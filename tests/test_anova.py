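import numpy as np
import pandas as pd
import pytest

import magest
from magest import RatingDataset, cell_means, gg_epsilon, mixed_anova
from magest.anova import _within_anova

from conftest import anova_frame, make_dataset


def _mixed_frame(lum, rng, n_per_group=(9, 11), L=8, group_shift=0.0, level_slope=0.3,
                 level_sd=None):
    """Random mixed-design trial frame (one 'rep' per cell)."""
    sids = [1, 2, 3, 4, 6, 7, 8, 9][:L]
    rows = []
    pid = 0
    for meth, npg in zip(["standard", "unidirectional"], n_per_group):
        for _ in range(npg):
            base = rng.normal()
            for l, sid in enumerate(sids):
                sd = 1.0 if level_sd is None else level_sd[l]
                y = base + level_slope * l + rng.normal(0, sd)
                if meth == "unidirectional":
                    y += group_shift
                rows.append(
                    (f"{meth}_{pid}", meth, sid, lum.intensity(sid), y,
                     "higher" if meth == "unidirectional" else np.nan)
                )
            pid += 1
    return RatingDataset(anova_frame(rows), lum)


class TestCellMeans:
    def test_identical_repetitions(self, lum):
        rows = [(0, "standard", 2, 1.8, 3.5, np.nan)] * 5
        ds = RatingDataset(anova_frame(rows), lum)
        cm = cell_means(ds)
        assert cm["response"].item() == 3.5

    def test_mean_of_two(self, lum):
        rows = [(0, "standard", 2, 1.8, 0.0, np.nan), (0, "standard", 2, 1.8, 2.0, np.nan)]
        ds = RatingDataset(anova_frame(rows), lum)
        assert cell_means(ds)["response"].item() == 1.0

    def test_study_shaped_data_has_eight_cells(self, lum):
        ds, _, _ = make_dataset(lum, n_participants=3, seed=0)
        cm = cell_means(ds)
        assert (cm.groupby("participant_id").size() == 8).all()


class TestGGEpsilon:
    def test_two_levels_exactly_one(self):
        S = np.array([[1.0, 0.3], [0.3, 2.0]])
        assert gg_epsilon(S) == 1.0

    def test_compound_symmetry_gives_one(self):
        S = 0.4 * np.ones((5, 5)) + 0.6 * np.eye(5)
        assert gg_epsilon(S) == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force_box_formula(self):
        # independent evaluation of Box's epsilon from element sums
        S = np.array(
            [
                [2.0, 0.8, 0.3, 0.1],
                [0.8, 1.5, 0.6, 0.2],
                [0.3, 0.6, 1.0, 0.4],
                [0.1, 0.2, 0.4, 0.7],
            ]
        )
        L = S.shape[0]
        # classical element-sum form of Box's formula
        sbar = S.mean()
        row = S.mean(axis=1)
        num = L**2 * (np.mean(np.diag(S)) - sbar) ** 2
        den = (L - 1) * (
            np.sum(S**2) - 2 * L * np.sum(row**2) + L**2 * sbar**2
        )
        assert gg_epsilon(S) == pytest.approx(num / den, rel=1e-10)
        # direct double-centering oracle
        H = np.eye(L) - np.ones((L, L)) / L
        Sc = H @ S @ H
        expected = np.trace(Sc) ** 2 / ((L - 1) * np.trace(Sc @ Sc))
        assert gg_epsilon(S) == pytest.approx(expected, rel=1e-12)
        assert 1.0 / (L - 1) < gg_epsilon(S) <= 1.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            gg_epsilon(np.ones((2, 3)))
        with pytest.raises(ValueError):
            gg_epsilon(np.array([[1.0, 0.9], [0.2, 1.0]]))
        with pytest.raises(ValueError):
            gg_epsilon(np.array([[1.0, 2.0], [2.0, 1.0]]))  # negative eigenvalue


class TestWithinAnova:
    def test_ss_match_sequential_ols_projection_oracle(self, lum):
        rng = np.random.default_rng(7)
        n, M, L = 3, 2, 3
        Y = rng.normal(size=(n, M, L)) + rng.normal(size=(n, 1, 1))
        res = _within_anova(Y.reshape(n, M * L), M, L)

        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        rows = [
            (i, m, l, Y[i, m, l]) for i in range(n) for m in range(M) for l in range(L)
        ]
        df = pd.DataFrame(rows, columns=["subj", "method", "stim", "y"])
        tab = anova_lm(
            smf.ols(
                "y ~ C(subj)+C(method)+C(stim)+C(method):C(stim)"
                "+C(subj):C(method)+C(subj):C(stim)",
                data=df,
            ).fit(),
            typ=1,
        )
        assert res["method"].ss == pytest.approx(tab.loc["C(method)", "sum_sq"], rel=1e-9)
        assert res["stimulus"].ss == pytest.approx(tab.loc["C(stim)", "sum_sq"], rel=1e-9)
        assert res["method:stimulus"].ss == pytest.approx(
            tab.loc["C(method):C(stim)", "sum_sq"], rel=1e-9
        )
        assert res["method"].ss_error == pytest.approx(
            tab.loc["C(subj):C(method)", "sum_sq"], rel=1e-9
        )
        assert res["stimulus"].ss_error == pytest.approx(
            tab.loc["C(subj):C(stim)", "sum_sq"], rel=1e-9
        )
        assert res["method:stimulus"].ss_error == pytest.approx(
            tab.loc["Residual", "sum_sq"], rel=1e-9
        )

    def test_within_design_on_simulated_study(self, lum):
        ds_std, pop, parts = make_dataset(lum, "standard", n_participants=10, seed=31)
        ds_rev = magest.simulate_ratings(parts, lum, "reversal", pop)
        both = ds_std.copy_with(
            pd.concat([ds_std.trials, ds_rev.trials], ignore_index=True)
        )
        clean, _ = magest.preprocess(both)
        logged = magest.log_responses(clean)
        res = mixed_anova(logged, between=None)
        assert res.design == "within"
        # a strong stimulus effect must emerge from a power-law observer
        assert res["stimulus"].p_gg < 1e-4
        assert 0 <= res["stimulus"].eta_g_sq <= 1


class TestMixedAnova:
    def test_matches_pingouin_on_study_shaped_data(self, lum):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        ds = _mixed_frame(lum, rng, group_shift=0.4,
                          level_sd=[1 + 0.2 * l for l in range(8)])
        res = mixed_anova(ds, between="method")
        df = ds.trials
        tab = pg.mixed_anova(
            data=df, dv="response", within="stimulus_id",
            subject="participant_id", between="method",
            correction=True, effsize="ng2",
        ).set_index("Source")
        assert res["method"].F == pytest.approx(tab.loc["method", "F"], rel=1e-9)
        assert res["stimulus"].F == pytest.approx(tab.loc["stimulus_id", "F"], rel=1e-9)
        assert res["method:stimulus"].F == pytest.approx(
            tab.loc["Interaction", "F"], rel=1e-9
        )
        assert res["stimulus"].eta_g_sq == pytest.approx(
            tab.loc["stimulus_id", "ng2"], rel=1e-9
        )
        assert res["method"].eta_g_sq == pytest.approx(tab.loc["method", "ng2"], rel=1e-9)
        # epsilon convention: ours pools the covariance within groups, which
        # equals pingouin's estimate applied to group-centered data
        wide = df.pivot(index="participant_id", columns="stimulus_id", values="response")
        meths = df.groupby("participant_id")["method"].first()
        centered = wide.copy()
        for m in meths.unique():
            idx = meths[meths == m].index
            centered.loc[idx] = wide.loc[idx] - wide.loc[idx].mean()
        assert res["stimulus"].epsilon == pytest.approx(
            float(pg.epsilon(centered, correction="gg")), rel=1e-6
        )

    def test_null_method_effect_is_tiny(self, lum):
        rng = np.random.default_rng(11)
        ds = _mixed_frame(lum, rng, n_per_group=(30, 30), group_shift=0.0,
                          level_slope=1.0)
        res = mixed_anova(ds, between="method")
        assert res["method"].eta_g_sq < 0.05

    def test_eta_g_invariant_to_constant_shift(self, lum):
        rng = np.random.default_rng(5)
        ds = _mixed_frame(lum, rng, group_shift=0.4)
        res1 = mixed_anova(ds, between="method")
        shifted = ds.copy_with(ds.trials.assign(response=ds.trials["response"] + 100.0))
        res2 = mixed_anova(shifted, between="method")
        for name in ("method", "stimulus", "method:stimulus"):
            assert res1[name].eta_g_sq == pytest.approx(res2[name].eta_g_sq, rel=1e-8)
            assert res1[name].F == pytest.approx(res2[name].F, rel=1e-8)

    def test_f_invariant_to_affine_rescale(self, lum):
        rng = np.random.default_rng(6)
        ds = _mixed_frame(lum, rng)
        res1 = mixed_anova(ds, between="method")
        scaled = ds.copy_with(
            ds.trials.assign(response=3.7 * ds.trials["response"] - 2.0)
        )
        res2 = mixed_anova(scaled, between="method")
        for name in ("method", "stimulus", "method:stimulus"):
            assert res1[name].F == pytest.approx(res2[name].F, rel=1e-8)

    def test_single_participant_group_rejected(self, lum):
        rng = np.random.default_rng(8)
        ds = _mixed_frame(lum, rng, n_per_group=(1, 5))
        with pytest.raises(ValueError):
            mixed_anova(ds, between="method")

    def test_p_monotone_in_f(self):
        from scipy import stats

        f = np.linspace(0.5, 10, 25)
        p = stats.f.sf(f, 3.2, 40.0)
        assert (np.diff(p) < 0).all()
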