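"""Sliding-window ANOVA and time-resolved standardized regression with
control-epoch significance calibration."""
import numpy as np
import pytest

from stnvalue.encoding import (NeuronEncodingModel, RegressorSet,
                               beta_significance, fit_betas, sliding_anova)
from stnvalue.spiketools import make_grid
from stnvalue._stats import two_way_anova


def toy_design(n=120, seed=0):
    rng = np.random.default_rng(seed)
    reward = np.tile([1, 2, 3], n // 3).astype(float)
    delay = rng.permuted(np.tile([4.55, 6.25], n // 2))
    dclass = np.where(delay < 5.4, "short", "long")
    return reward, delay, dclass, rng


class TestSlidingAnova:
    def test_oracle_equivalence_statsmodels(self):
        import pandas as pd
        import statsmodels.api as sm
        from statsmodels.formula.api import ols
        reward, delay, dclass, rng = toy_design(60, seed=3)
        counts = rng.poisson(3.0, (60, 4)).astype(float)
        res = two_way_anova(counts, reward, dclass)
        for b in range(4):
            df = pd.DataFrame({"y": counts[:, b], "r": reward, "d": dclass})
            ora = sm.stats.anova_lm(ols("y ~ C(r) * C(d)", df).fit(), typ=2)
            assert res["reward"][0][b] == pytest.approx(
                ora.loc["C(r)", "F"], abs=1e-8)
            assert res["delay"][0][b] == pytest.approx(
                ora.loc["C(d)", "F"], abs=1e-8)
            assert res["interaction"][0][b] == pytest.approx(
                ora.loc["C(r):C(d)", "F"], abs=1e-8)

    def test_null_neuron_rarely_flagged(self):
        rng = np.random.default_rng(11)
        grid = make_grid("analysis")
        flagged = 0
        n_neurons = 25
        for _ in range(n_neurons):
            reward, delay, dclass, _ = toy_design(120, seed=rng.integers(1e6))
            counts = rng.poisson(3.0, (120, grid.n_bins)).astype(float)
            res = sliding_anova(counts, reward, dclass, grid.centers)
            flagged += res.flags["reward"].sum() + res.flags["delay"].sum()
        # expected flag rate per test = 0.05/174; over 25*174*2 tests ~ 2.5
        assert flagged <= 12

    def test_planted_phase1_reward_gain_localized(self, small_dataset):
        ds = small_dataset
        tuned = ds.truth[ds.truth.category == "Discounting-"].iloc[0]
        nid = int(tuned.neuron_id)
        sess = ds.trials[ds.trials.session_id
                         == ds.spikes.session_of[nid]].reset_index(drop=True)
        ok = (sess["outcome"] == "completed").to_numpy()
        trains = [t for t, keep in zip(ds.spikes.spikes[nid], ok) if keep]
        from stnvalue.spiketools import window_counts
        grid = make_grid("analysis")
        counts = window_counts(trains, grid)
        res = sliding_anova(counts, sess["reward_size"].to_numpy()[ok],
                            sess["delay_class"].to_numpy()[ok], grid.centers)
        assert res.task_related

    def test_constant_counts_skipped(self):
        reward, delay, dclass, _ = toy_design(60)
        counts = np.full((60, 5), 7.0)
        res = sliding_anova(counts, reward, dclass, np.arange(5) * 0.02)
        assert res.n_skipped == 5
        assert not res.task_related

    def test_sparse_cells_rejected(self):
        counts = np.ones((5, 3))
        with pytest.raises(ValueError):
            sliding_anova(counts, [1, 1, 2, 2, 3], ["s", "l", "s", "l", "s"],
                          np.arange(3))


class TestFitBetas:
    def test_noiseless_linear_model(self):
        reward, delay, dclass, rng = toy_design(120, seed=4)
        grid = make_grid("analysis", width=0.1, step=0.1)
        zr = (reward - reward.mean()) / reward.std()
        counts = np.tile((0.8 * zr)[:, None], (1, grid.n_bins))
        reg = RegressorSet(reward=reward, delay=delay)
        series = fit_betas(counts, reg, grid)
        np.testing.assert_allclose(series.coef("reward"), 0.8, atol=1e-10)
        np.testing.assert_allclose(series.coef("delay"), 0.0, atol=1e-10)

    def test_normal_equations_oracle(self):
        """Betas match an explicit (X'X)^-1 X'y solve on small designs."""
        rng = np.random.default_rng(5)
        grid = make_grid("analysis", width=0.5, step=0.5)
        for _ in range(20):
            n = 25
            reward = rng.choice([1.0, 2.0, 3.0], n)
            delay = rng.uniform(3.5, 7.3, n)
            counts = rng.poisson(4.0, (n, grid.n_bins)).astype(float)
            reg = RegressorSet(reward=reward, delay=delay)
            series = fit_betas(counts, reg, grid)
            for b in range(grid.n_bins):
                zr = (reward - reward.mean()) / reward.std()
                zd = (delay - delay.mean()) / delay.std()
                y = counts[:, b]
                X = np.column_stack([np.ones(n), zr, zd])
                beta = np.linalg.inv(X.T @ X) @ X.T @ y
                np.testing.assert_allclose(series.betas[b], beta, atol=1e-10)

    def test_permuted_counts_betas_near_zero(self):
        rng = np.random.default_rng(6)
        reward, delay, dclass, _ = toy_design(180, seed=6)
        grid = make_grid("analysis", width=0.1, step=0.1)
        zr = (reward - reward.mean()) / reward.std()
        counts = np.tile((5 + 2 * zr)[:, None], (1, grid.n_bins))
        counts = rng.permuted(counts, axis=0)
        reg = RegressorSet(reward=reward, delay=delay)
        series = fit_betas(counts, reg, grid)
        assert abs(series.coef("reward").mean()) < 0.1

    def test_standardization_invariance(self):
        """Rescaling raw regressors leaves standardized betas unchanged."""
        rng = np.random.default_rng(7)
        reward, delay, dclass, _ = toy_design(90, seed=7)
        counts = rng.poisson(3.0, (90, 4)).astype(float)
        grid = make_grid("analysis", width=0.875, step=0.875)
        reg1 = RegressorSet(reward=reward, delay=delay)
        reg2 = RegressorSet(reward=reward * 137.0, delay=delay * 0.003)
        b1 = fit_betas(counts, reg1, grid)
        b2 = fit_betas(counts, reg2, grid)
        np.testing.assert_allclose(b1.betas, b2.betas, atol=1e-10)

    def test_constant_regressor_flagged(self):
        rng = np.random.default_rng(8)
        counts = rng.poisson(3.0, (40, 2)).astype(float)
        grid = make_grid("analysis", width=1.75, step=1.75)
        reg = RegressorSet(reward=np.full(40, 2.0), delay=rng.uniform(4, 6, 40))
        series = fit_betas(counts, reg, grid)
        assert np.isnan(series.coef("reward")).all()
        assert series.undefined[series.names.index("reward")]

    def test_too_few_trials_rejected(self):
        grid = make_grid("analysis", width=1.75, step=1.75)
        with pytest.raises(ValueError):
            fit_betas(np.ones((10, 2)), RegressorSet(
                reward=np.arange(10.0), delay=np.arange(10.0)), grid)


class TestBetaSignificance:
    def _series(self, betas, control, grid_c):
        from stnvalue.encoding import BetaSeries
        names = ("const", "reward", "delay")
        nb = betas.shape[0]
        test = BetaSeries(centers=np.arange(nb, dtype=float), names=names,
                          betas=betas,
                          control_betas=np.empty((0, 3)),
                          control_mean=np.full(3, np.nan),
                          control_sd=np.full(3, np.nan))
        ctrl = BetaSeries(centers=grid_c, names=names, betas=control,
                          control_betas=np.empty((0, 3)),
                          control_mean=np.full(3, np.nan),
                          control_sd=np.full(3, np.nan))
        return test, ctrl

    def test_beta_equal_to_control_mean_not_flagged(self, rng):
        control = rng.normal(0.2, 0.1, (47, 3))
        betas = np.tile(control.mean(axis=0), (5, 1))
        test, ctrl = self._series(betas, control, np.arange(47.0))
        out = beta_significance(test, ctrl)
        assert not out.sig.any()
        np.testing.assert_allclose(out.p, 1.0, atol=1e-12)

    def test_extreme_beta_flagged_closed_form(self, rng):
        from scipy import stats
        control = rng.normal(0.0, 0.05, (47, 3))
        mean_c = control.mean(axis=0)
        sd_c = control.std(axis=0, ddof=1)
        betas = (mean_c + 10 * sd_c)[None, :]
        test, ctrl = self._series(betas, control, np.arange(47.0))
        out = beta_significance(test, ctrl)
        assert out.sig.all()
        t_expect = 10.0 / np.sqrt(1 + 1 / 47)
        p_expect = 2 * stats.t.sf(t_expect, df=46)
        np.testing.assert_allclose(out.p[0], p_expect, rtol=1e-10)

    def test_null_calibration_five_percent(self, rng):
        """Under the null, ~5% of bins are flagged per coefficient."""
        n_flag, n_tot = 0, 0
        for _ in range(200):
            control = rng.normal(0.0, 1.0, (47, 1))
            betas = rng.normal(0.0, 1.0, (20, 1))
            test, ctrl = self._series(
                np.repeat(betas, 3, axis=1), np.repeat(control, 3, axis=1),
                np.arange(47.0))
            out = beta_significance(test, ctrl)
            n_flag += out.sig[:, 1].sum()
            n_tot += out.sig.shape[0]
        assert n_flag / n_tot == pytest.approx(0.05, abs=0.015)

    def test_zero_control_sd_fallback(self):
        control = np.zeros((47, 3))
        betas = np.array([[0.0, 0.5, 0.0]])
        test, ctrl = self._series(betas, control, np.arange(47.0))
        out = beta_significance(test, ctrl)
        assert bool(out.sig[0, 1])
        assert not out.sig[0, 0]


class TestNeuronEncodingModel:
    def test_planted_neuron_recovered_with_and_without_eye(self, small_dataset):
        ds = small_dataset
        from stnvalue.pipeline import neuron_inputs
        inputs = {nid: (t, r) for nid, t, r in neuron_inputs(ds)}
        tuned = ds.truth[ds.truth.category == "Discounting-"].iloc[0]
        nid = int(tuned.neuron_id)
        trains, reg = inputs[nid]
        res = NeuronEncodingModel(trains, reg, neuron_id=nid).fit()
        assert res.task_related
        # reward coding positive, delay negative in phase 1
        ph1 = res.betas.centers < 2.0
        sigR = res.betas.sig_of("reward") & ph1
        assert res.betas.coef("reward")[sigR].mean() > 0
        res_noeye = NeuronEncodingModel(trains, reg, neuron_id=nid).fit(
            include_eye=False)
        assert res_noeye.task_related
        assert "eye_pos" not in res_noeye.betas.names
        # eye exclusion keeps the reward coefficient series similar (the
        # planted eye offsets are reward-correlated, so not identical)
        r_full = res.betas.coef("reward")
        r_lean = res_noeye.betas.coef("reward")
        assert np.corrcoef(r_full, r_lean)[0, 1] > 0.5

    def test_control_population_is_47(self, small_dataset):
        ds = small_dataset
        from stnvalue.pipeline import neuron_inputs
        nid, trains, reg = neuron_inputs(ds)[0]
        res = NeuronEncodingModel(trains, reg, neuron_id=nid).fit()
        assert res.control.betas.shape[0] == 47
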