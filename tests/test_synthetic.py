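"""Ground-truth generator: balanced designs, behavioral convergence,
Poisson count statistics, eye signals and the planted anatomical gradient."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stnvalue.config import ConfigError, SimConfig
from stnvalue.synthetic import (assign_anatomy, design_standardizers,
                                draw_ground_truth, generate_dataset,
                                rejection_probability, simulate_eye,
                                simulate_spikes, simulate_trials)
from stnvalue.spiketools import make_grid, window_counts
from stnvalue.encoding import continuous_anova


class TestSimulateTrials:
    def test_balanced_conditions_per_session(self):
        cfg = SimConfig(n_sessions=3, trials_per_session=36, n_neurons=1, seed=0)
        trials = simulate_trials(cfg)
        for _, sess in trials.groupby("session_id"):
            counts = sess.groupby(["reward_size", "delay_class"]).size()
            assert len(counts) == 6 and (counts == 6).all()

    def test_delays_within_condition_ranges(self):
        cfg = SimConfig(n_sessions=2, trials_per_session=60, n_neurons=1, seed=1)
        trials = simulate_trials(cfg)
        short = trials[trials.delay_class == "short"]["delay_s"]
        long = trials[trials.delay_class == "long"]["delay_s"]
        assert short.between(*cfg.delay_short_range_s).all()
        assert long.between(*cfg.delay_long_range_s).all()

    def test_no_discounting_no_rejections(self):
        cfg = SimConfig(n_sessions=2, trials_per_session=36, n_neurons=1,
                        k_true=0.0, a_true=1e9, seed=2)
        trials = simulate_trials(cfg)
        assert (trials["outcome"] == "completed").all()

    def test_rejection_probability_ordering(self):
        # smaller rewards and longer delays are rejected more often
        p_small_long = rejection_probability(1, 6.25, 1.62, 40.0)
        p_large_short = rejection_probability(3, 4.55, 1.62, 40.0)
        assert p_small_long > p_large_short

    def test_rejection_rate_matches_binomial_oracle(self):
        # 10k trials at one fixed condition: empirical rate within 3 SE
        cfg = SimConfig(n_sessions=1, trials_per_session=10002,
                        reward_levels=(2,), n_neurons=1, seed=3)
        trials = simulate_trials(cfg)
        sub = trials[trials.delay_class == "long"]
        p_exp = rejection_probability(2, sub["delay_s"].to_numpy(),
                                      cfg.k_true, cfg.a_true).mean()
        emp = (sub["outcome"] == "rejected").mean()
        se = np.sqrt(p_exp * (1 - p_exp) / len(sub))
        assert abs(emp - p_exp) < 3 * se

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            simulate_trials(SimConfig(trials_per_session=0))
        with pytest.raises(ConfigError):
            SimConfig(k_true=-1).validate()
        with pytest.raises(ConfigError):
            SimConfig(category_mix={"untuned": 0.5}).validate()

    def test_seed_reproducibility(self):
        cfg = SimConfig(n_sessions=2, trials_per_session=36, n_neurons=1, seed=9)
        t1, t2 = simulate_trials(cfg), simulate_trials(cfg)
        pd.testing.assert_frame_equal(t1, t2)


@pytest.fixture(scope="module")
def untuned():
    cfg = SimConfig(n_sessions=1, trials_per_session=120, n_neurons=8,
                    category_mix={"untuned": 1.0}, transient_amp=0.0,
                    seed=5)
    trials = simulate_trials(cfg)
    spikes, truth = simulate_spikes(cfg, trials)
    return cfg, spikes, truth


class TestSimulateSpikes:

    def test_untuned_fano_near_one(self, untuned):
        cfg, spikes, truth = untuned
        grid = make_grid("analysis", width=0.1, step=0.1)
        fanos = []
        for nid in spikes.neuron_ids:
            c = window_counts(spikes.spikes[nid], grid).astype(float)
            fanos.append((c.var(axis=0, ddof=1) / c.mean(axis=0)).mean())
        assert np.mean(fanos) == pytest.approx(1.0, abs=0.05)

    def test_untuned_counts_pass_poisson_dispersion(self, untuned):
        # chi-square dispersion test at alpha=0.01 passes for >=95% of neurons
        cfg, spikes, truth = untuned
        grid = make_grid("analysis", width=0.2, step=0.2)
        n_pass = 0
        for nid in spikes.neuron_ids:
            c = window_counts(spikes.spikes[nid], grid).astype(float)
            col = c[:, 3]
            n = col.size
            disp = (n - 1) * col.var(ddof=1) / col.mean()
            lo, hi = stats.chi2.ppf([0.005, 0.995], n - 1)
            n_pass += lo < disp < hi
        assert n_pass >= 0.95 * len(spikes.neuron_ids) - 1e-9

    def test_mean_count_matches_poisson_expectation(self, untuned):
        cfg, spikes, truth = untuned
        grid = make_grid("analysis", width=0.2, step=0.2)
        for nid in spikes.neuron_ids[:4]:
            b = truth.set_index("neuron_id").loc[nid, "baseline_hz"]
            c = window_counts(spikes.spikes[nid], grid)
            se = np.sqrt(0.2 * b / c.size)
            assert c.mean() == pytest.approx(0.2 * b, abs=4 * se)

    def test_empty_trials_rejected(self):
        cfg = SimConfig(seed=0)
        with pytest.raises(ConfigError):
            simulate_spikes(cfg, pd.DataFrame())

    def test_tuned_neuron_modulates_rate_by_condition(self):
        cfg = SimConfig(n_sessions=1, trials_per_session=120, n_neurons=2,
                        category_mix={"Discounting-": 1.0}, encoding_gain=0.6,
                        seed=6)
        trials = simulate_trials(cfg)
        spikes, truth = simulate_spikes(cfg, trials)
        nid = int(spikes.neuron_ids[0])
        grid = make_grid("analysis", width=1.0, step=1.0)
        counts = window_counts(spikes.spikes[nid], grid)[:, 0]
        r = trials["reward_size"].to_numpy()
        assert counts[r == 3].mean() > counts[r == 1].mean()


class TestSimulateEye:
    def test_velocity_of_constant_position_is_zero(self):
        pos = np.full((3, 100), 2.5)
        vel = np.gradient(pos, 1 / 240.0, axis=1)
        assert np.allclose(vel, 0.0)

    def test_null_offsets_no_significant_bins(self):
        cfg = SimConfig(n_sessions=1, trials_per_session=120, n_neurons=1,
                        eye_reward_gain_deg=0.0, eye_delay_gain_deg=0.0,
                        k_true=0.0, a_true=1e9, seed=7)
        trials = simulate_trials(cfg)
        eye = simulate_eye(trials, cfg)
        res = continuous_anova(eye.position[0], eye.times,
                               trials["reward_size"], trials["delay_class"])
        total_flags = sum(res.flags[e].sum() for e in res.flags)
        assert total_flags == 0

    def test_planted_reward_offset_detected(self):
        cfg = SimConfig(n_sessions=1, trials_per_session=180, n_neurons=1,
                        eye_reward_gain_deg=1.5, eye_delay_gain_deg=0.0,
                        k_true=0.0, a_true=1e9, seed=8)
        trials = simulate_trials(cfg)
        eye = simulate_eye(trials, cfg)
        res = continuous_anova(eye.position[0], eye.times,
                               trials["reward_size"], trials["delay_class"])
        assert res.flags["reward"].sum() > 0
        assert res.flags["delay"].sum() == 0


class TestAssignAnatomy:
    def test_gradient_strength_recovered(self, rng):
        cfg = SimConfig(n_neurons=231, gradient_strength=0.5, seed=12)
        truth = draw_ground_truth(cfg, np.random.default_rng(12))
        pos = assign_anatomy(cfg, truth, rng=np.random.default_rng(13))
        d = np.asarray(cfg.gradient_direction)
        d = d / np.linalg.norm(d)
        proj = pos[["x_mm", "y_mm", "z_mm"]].to_numpy() @ d
        rho = stats.spearmanr(proj, truth["gain"]).statistic
        assert rho == pytest.approx(0.5, abs=0.15)

    def test_zero_gradient_uncorrelated(self):
        cfg = SimConfig(n_neurons=231, gradient_strength=0.0, seed=14)
        truth = draw_ground_truth(cfg, np.random.default_rng(14))
        pos = assign_anatomy(cfg, truth, rng=np.random.default_rng(15))
        d = np.asarray(cfg.gradient_direction)
        proj = pos[["x_mm", "y_mm", "z_mm"]].to_numpy() @ (d / np.linalg.norm(d))
        rho = stats.spearmanr(proj, truth["gain"]).statistic
        assert abs(rho) < 0.15

    def test_positions_inside_volume(self):
        from stnvalue.synthetic import STN_SEMI_AXES
        cfg = SimConfig(n_neurons=100, seed=16)
        truth = draw_ground_truth(cfg, np.random.default_rng(16))
        pos = assign_anatomy(cfg, truth, rng=np.random.default_rng(17))
        xyz = pos[["x_mm", "y_mm", "z_mm"]].to_numpy()
        r2 = ((xyz / np.array(STN_SEMI_AXES)) ** 2).sum(axis=1)
        assert (r2 <= 1.0 + 1e-9).all()


class TestDeterminism:
    def test_fixed_seed_identical_datasets(self):
        cfg = SimConfig(n_sessions=2, trials_per_session=36, n_neurons=4,
                        seed=42)
        d1, d2 = generate_dataset(cfg), generate_dataset(cfg)
        pd.testing.assert_frame_equal(d1.trials, d2.trials)
        pd.testing.assert_frame_equal(d1.truth, d2.truth)
        for nid in d1.spikes.neuron_ids:
            for a, b in zip(d1.spikes.spikes[nid], d2.spikes.spikes[nid]):
                np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(d1.eye.position[0], d2.eye.position[0])

    def test_behavioral_means_converge_to_model(self):
        # 10k trials/condition: empirical condition means within 3 SE
        cfg = SimConfig(n_sessions=10, trials_per_session=6000, n_neurons=1,
                        seed=18)
        trials = simulate_trials(cfg)
        for (r, dc), cell in trials.groupby(["reward_size", "delay_class"]):
            p = rejection_probability(r, cell["delay_s"].to_numpy(),
                                      cfg.k_true, cfg.a_true).mean()
            emp = (cell["outcome"] == "rejected").mean()
            se = np.sqrt(p * (1 - p) / len(cell))
            assert abs(emp - p) < 3 * se


def test_design_standardizers_zero_mean_unit_sd():
    cfg = SimConfig()
    zr, zd = design_standardizers(cfg)
    z = zr(np.repeat([1, 2, 3], 2))
    assert z.mean() == pytest.approx(0, abs=1e-12)
    assert z.std() == pytest.approx(1, abs=1e-12)
    zD = zd(np.repeat([4.55, 6.25], 3))
    assert zD.mean() == pytest.approx(0, abs=1e-12)
    assert zD.std() == pytest.approx(1, abs=1e-12)
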