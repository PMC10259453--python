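"""Synthetic ground-truth generator.

Emulates the study conditions of the delayed-reward recordings: a balanced
3x2 reward-by-delay design in pseudo-random order, Bernoulli trial
rejections whose condition means follow the hyperbolic rejection model
E = (1 + kD)/(aR), inhomogeneous-Poisson spike trains with a cue-locked
transient plus phase-dependent reward/delay gain modulation (including
Discounting- -> Compounding+ switchers), AR(1) eye-position traces with
condition-dependent post-cue offsets, and anatomical coordinates carrying a
planted dorso-posterior gradient of encoding strength.

Every artifact has its own RNG stream derived from the master seed, so each
stage is independently reproducible.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import SimConfig, ConfigError

__all__ = [
    "SpikeData",
    "EyeData",
    "Dataset",
    "design_standardizers",
    "simulate_trials",
    "simulate_spikes",
    "simulate_eye",
    "assign_anatomy",
    "generate_dataset",
]

#: ellipsoid semi-axes (mm) of the nucleus-like recording volume (x, y, z)
STN_SEMI_AXES = (1.5, 4.0, 2.0)

# category -> sign of (w_R, w_D) per phase; switchers flip at switch_time_s
_CATEGORY_SIGNS = {
    "Discounting-": ((+1, -1), (+1, -1)),
    "Discounting+": ((-1, +1), (-1, +1)),
    "Compounding+": ((+1, +1), (+1, +1)),
    "Compounding-": ((-1, -1), (-1, -1)),
    "switcher": ((+1, -1), (+1, +1)),
    "untuned": ((0, 0), (0, 0)),
}
_PHASE_LABELS = {
    "Discounting-": ("Discounting-", "Discounting-"),
    "Discounting+": ("Discounting+", "Discounting+"),
    "Compounding+": ("Compounding+", "Compounding+"),
    "Compounding-": ("Compounding-", "Compounding-"),
    "switcher": ("Discounting-", "Compounding+"),
    "untuned": ("untuned", "untuned"),
}


@dataclass
class SpikeData:
    """Per-neuron spike times (s, cue-aligned) for the neuron's session."""

    neuron_ids: np.ndarray
    session_of: dict            # neuron_id -> session_id
    trial_ids: dict             # neuron_id -> array of trial ids (session order)
    spikes: dict                # neuron_id -> list of per-trial spike-time arrays
    t_start: float = -1.2
    t_stop: float = 3.7

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for nid in self.neuron_ids:
            sid = self.session_of[nid]
            for tid, times in zip(self.trial_ids[nid], self.spikes[nid]):
                for t in times:
                    rows.append((nid, sid, tid, t))
        return pd.DataFrame(
            rows, columns=["neuron_id", "session_id", "trial_id", "spike_time_s"])


@dataclass
class EyeData:
    """Tangential eye position/velocity per session, cue-aligned, 240 Hz."""

    times: np.ndarray                       # shared sample times (s)
    position: dict = field(default_factory=dict)   # session_id -> (trials, T)
    velocity: dict = field(default_factory=dict)


@dataclass
class Dataset:
    """Bundle of all simulated artifacts for one run."""

    config: SimConfig
    trials: pd.DataFrame
    spikes: SpikeData
    truth: pd.DataFrame         # per-neuron planted ground truth
    eye: EyeData
    truth_params: dict          # scalar truths (k_true, a_true, gradient)


def design_standardizers(config: SimConfig):
    """Z-scoring callables for reward and delay over the 6-condition design.

    Reward levels appear once per delay class; the delay dimension is
    standardized over the two class midpoints (applied to realized delays).
    """
    rewards = np.repeat(np.asarray(config.reward_levels, dtype=float), 2)
    r_mean, r_sd = rewards.mean(), rewards.std()
    mids = np.array([
        np.mean(config.delay_short_range_s), np.mean(config.delay_long_range_s)])
    d_mean, d_sd = mids.mean(), np.repeat(mids, len(config.reward_levels)).std()

    def z_reward(r):
        return (np.asarray(r, dtype=float) - r_mean) / r_sd

    def z_delay(d):
        return (np.asarray(d, dtype=float) - d_mean) / d_sd

    return z_reward, z_delay


def rejection_probability(R, D, k, a):
    """Model rejection probability clip((1 + k*D) / (a*R), 0, 1)."""
    return np.clip((1.0 + k * np.asarray(D, dtype=float)) / (a * np.asarray(R, dtype=float)), 0.0, 1.0)


def _rng_streams(seed: int):
    ss = np.random.SeedSequence(seed)
    kids = ss.spawn(4)
    return {name: np.random.default_rng(k)
            for name, k in zip(("trials", "spikes", "eye", "anatomy"), kids)}


def _truncnorm_delays(lo, hi, size, rng):
    mid = 0.5 * (lo + hi)
    sd = (hi - lo) / 4.0
    a, b = (lo - mid) / sd, (hi - mid) / sd
    return stats.truncnorm.rvs(a, b, loc=mid, scale=sd, size=size, random_state=rng)


def simulate_trials(config: SimConfig, rng=None) -> pd.DataFrame:
    """Balanced pseudo-random trial tables with hyperbolic rejection behavior.

    Each session contains the 6 reward-by-delay conditions in shuffled
    balanced order; realized delays are truncated Gaussians centered on the
    range midpoint (sd = range/4); the per-trial rejection outcome is
    Bernoulli with p = clip((1 + k*D)/(a*R), 0, 1).
    """
    config.validate()
    if rng is None:
        rng = _rng_streams(config.seed)["trials"]
    n_cond = 2 * len(config.reward_levels)
    reps = config.trials_per_session // n_cond
    conditions = [(r, dc) for r in config.reward_levels for dc in ("short", "long")]
    cond_r = np.array([c[0] for c in conditions], dtype=float)
    cond_dc = np.array([c[1] for c in conditions])
    ranges = {"short": config.delay_short_range_s, "long": config.delay_long_range_s}

    n_total = config.n_sessions * config.trials_per_session
    order = np.empty((config.n_sessions, config.trials_per_session), dtype=int)
    base = np.repeat(np.arange(n_cond), reps)
    for sid in range(config.n_sessions):
        order[sid] = rng.permutation(base)
    ci = order.ravel()
    r = cond_r[ci]
    dc = cond_dc[ci]
    delay = np.empty(n_total)
    for klass, (lo, hi) in ranges.items():
        mask = dc == klass
        delay[mask] = _truncnorm_delays(lo, hi, int(mask.sum()), rng)
    p = rejection_probability(r, delay, config.k_true, config.a_true)
    rejected = rng.random(n_total) < p
    reject_time = np.where(rejected, rng.uniform(0.0, 1.0, n_total) * delay,
                           np.nan)
    return pd.DataFrame({
        "session_id": np.repeat(np.arange(config.n_sessions),
                                config.trials_per_session),
        "trial_id": np.tile(np.arange(config.trials_per_session),
                            config.n_sessions),
        "reward_size": r.astype(int),
        "delay_class": dc,
        "delay_s": delay,
        "outcome": np.where(rejected, "rejected", "completed"),
        "reject_time_s": reject_time,
    })


def _transient(times: np.ndarray, config: SimConfig) -> np.ndarray:
    """Cue-locked log-rate bump peaking ~150 ms post cue."""
    return config.transient_amp * np.exp(
        -0.5 * ((times - config.transient_peak_s) / config.transient_sd_s) ** 2)


def draw_ground_truth(config: SimConfig, rng) -> pd.DataFrame:
    """Planted per-neuron categories, gains, baselines and waveform scalars."""
    cats = list(config.category_mix)
    probs = np.array([config.category_mix[c] for c in cats])
    category = rng.choice(cats, size=config.n_neurons, p=probs)
    gain = config.encoding_gain * np.exp(rng.normal(0.0, 0.25, config.n_neurons))
    gain[category == "untuned"] = 0.0
    lo, hi = config.baseline_rate_range_hz
    baseline = rng.uniform(lo, hi, config.n_neurons)
    width = np.clip(rng.normal(0.6, 0.1, config.n_neurons), 0.2, None)
    amp = np.clip(rng.normal(150.0, 40.0, config.n_neurons), 30.0, None)

    rows = []
    for i in range(config.n_neurons):
        c = category[i]
        (s1r, s1d), (s2r, s2d) = _CATEGORY_SIGNS[c]
        lab1, lab2 = _PHASE_LABELS[c]
        rows.append({
            "neuron_id": i,
            "session_id": i % config.n_sessions,
            "category": c,
            "category_phase1": lab1,
            "category_phase2": lab2,
            "w_R_phase1": s1r * gain[i],
            "w_D_phase1": s1d * gain[i],
            "w_R_phase2": s2r * gain[i],
            "w_D_phase2": s2d * gain[i],
            "w_RD": (config.interaction_gain if c != "untuned" else 0.0),
            "baseline_hz": baseline[i],
            "gain": gain[i],
            "spike_width_ms": width[i],
            "spike_amp_uv": amp[i],
        })
    return pd.DataFrame(rows)


def simulate_spikes(config: SimConfig, trials: pd.DataFrame, rng=None,
                    truth: pd.DataFrame | None = None):
    """Inhomogeneous-Poisson spike trains with planted encoding patterns.

    Per neuron and trial, spikes are drawn on
    ``[spike_t_start_s, spike_t_stop_s]`` around cue onset with
    log-rate = log(b) + transient(t) + s(t) * (w_R z(R) + w_D z(D)
    + w_RD z(R)z(D)); the phase profile s(t) switches the planted signs at
    ``switch_time_s`` (switcher neurons flip from Discounting- to
    Compounding+). The exponential link keeps rates positive by construction.

    Returns (SpikeData, truth DataFrame).
    """
    config.validate()
    if trials.empty:
        raise ConfigError("trial table is empty")
    if rng is None:
        rng = _rng_streams(config.seed)["spikes"]
    if truth is None:
        truth = draw_ground_truth(config, rng)
    z_reward, z_delay = design_standardizers(config)

    dt = 0.001
    edges = np.arange(config.spike_t_start_s, config.spike_t_stop_s + dt / 2, dt)
    centers = edges[:-1] + dt / 2
    trans = _transient(centers, config)
    in_phase1 = (centers >= 0.0) & (centers < config.switch_time_s)
    in_phase2 = centers >= config.switch_time_s

    by_session = dict(tuple(trials.groupby("session_id")))
    neuron_ids = truth["neuron_id"].to_numpy()
    session_of, trial_ids, spikes = {}, {}, {}
    for row in truth.itertuples(index=False):
        sid = row.session_id
        sess = by_session[sid]
        zR = z_reward(sess["reward_size"].to_numpy())
        zD = z_delay(sess["delay_s"].to_numpy())
        m1 = row.w_R_phase1 * zR + row.w_D_phase1 * zD + row.w_RD * zR * zD
        m2 = row.w_R_phase2 * zR + row.w_D_phase2 * zD + row.w_RD * zR * zD
        log_rate = (np.log(row.baseline_hz) + trans[None, :]
                    + np.outer(m1, in_phase1) + np.outer(m2, in_phase2))
        counts = rng.poisson(np.exp(log_rate) * dt)
        per_trial = counts.sum(axis=1)
        lefts = np.repeat(np.broadcast_to(edges[:-1], counts.shape).ravel(),
                          counts.ravel())
        times = lefts + rng.uniform(0.0, dt, lefts.size)
        splits = np.cumsum(per_trial)[:-1]
        trains = [np.sort(t) for t in np.split(times, splits)]
        nid = int(row.neuron_id)
        session_of[nid] = int(sid)
        trial_ids[nid] = sess["trial_id"].to_numpy()
        spikes[nid] = trains

    data = SpikeData(neuron_ids=neuron_ids, session_of=session_of,
                     trial_ids=trial_ids, spikes=spikes,
                     t_start=config.spike_t_start_s, t_stop=config.spike_t_stop_s)
    return data, truth


def simulate_eye(trials: pd.DataFrame, config: SimConfig, rng=None) -> EyeData:
    """Tangential eye position as AR(1) noise plus condition-dependent
    post-cue offsets; velocity is the first difference divided by the step."""
    config.validate()
    if rng is None:
        rng = _rng_streams(config.seed)["eye"]
    z_reward, z_delay = design_standardizers(config)
    dt = 1.0 / config.eye_rate_hz
    times = np.arange(config.spike_t_start_s, config.spike_t_stop_s, dt)
    T = times.size
    phi = config.eye_ar_coef
    innov_sd = config.eye_noise_sd_deg * np.sqrt(1.0 - phi**2)
    ramp = np.clip(times / config.eye_ramp_s, 0.0, 1.0) * (times >= 0)

    eye = EyeData(times=times)
    for sid, sess in trials.groupby("session_id"):
        n = len(sess)
        eps = rng.normal(0.0, innov_sd, (n, T))
        ar = np.empty((n, T))
        ar[:, 0] = rng.normal(0.0, config.eye_noise_sd_deg, n)
        for j in range(1, T):
            ar[:, j] = phi * ar[:, j - 1] + eps[:, j]
        amp = (config.eye_reward_gain_deg * z_reward(sess["reward_size"].to_numpy())
               + config.eye_delay_gain_deg * z_delay(sess["delay_s"].to_numpy()))
        pos = ar + amp[:, None] * ramp[None, :]
        vel = np.gradient(pos, dt, axis=1)
        eye.position[int(sid)] = pos.astype(np.float32)
        eye.velocity[int(sid)] = vel.astype(np.float32)
    return eye


def _sample_ellipsoid(n, semi_axes, rng):
    out = np.empty((n, 3))
    filled = 0
    semi = np.asarray(semi_axes)
    while filled < n:
        cand = rng.uniform(-1.0, 1.0, (2 * (n - filled) + 8, 3))
        ok = (cand**2).sum(axis=1) <= 1.0
        take = cand[ok][: n - filled]
        out[filled:filled + take.shape[0]] = take * semi
        filled += take.shape[0]
    return out


def assign_anatomy(config: SimConfig, truth: pd.DataFrame, rng=None) -> pd.DataFrame:
    """Coordinates in an ellipsoidal nucleus-like volume whose projection on
    ``gradient_direction`` rank-correlates with planted encoding gain at
    Spearman rho ~ ``gradient_strength``.

    The coupling is a Gaussian-copula rank match: positions are sampled
    first (so the point cloud is unchanged), then reassigned to neurons so
    that projection ranks follow a latent variable correlated with the
    gain's normal scores. The copula correlation is calibrated by bisection
    against the target Spearman rho, which also compensates attenuation from
    ties among untuned (zero-gain) neurons.
    """
    config.validate()
    if rng is None:
        rng = _rng_streams(config.seed)["anatomy"]
    n = len(truth)
    pts = _sample_ellipsoid(n, STN_SEMI_AXES, rng)
    d = np.asarray(config.gradient_direction, dtype=float)
    d = d / np.linalg.norm(d)
    g = truth["gain"].to_numpy()

    target = config.gradient_strength
    if target > 0 and np.unique(g).size > 1:
        ranks = stats.rankdata(g)
        zg = stats.norm.ppf((ranks - 0.5) / n)
        zg = (zg - zg.mean()) / zg.std()
        cal_rng = np.random.default_rng(rng.integers(2**31))

        def mean_spearman(c, reps=120):
            eps = cal_rng.standard_normal((reps, n))
            u = c * zg[None, :] + np.sqrt(1.0 - c * c) * eps
            rs = [stats.spearmanr(u[i], g).statistic for i in range(reps)]
            return float(np.mean(rs))

        lo_c, hi_c = 0.0, 1.0
        if mean_spearman(1.0) <= target:
            c_star = 1.0
        else:
            for _ in range(10):
                mid = 0.5 * (lo_c + hi_c)
                if mean_spearman(mid) < target:
                    lo_c = mid
                else:
                    hi_c = mid
            c_star = 0.5 * (lo_c + hi_c)
        u = c_star * zg + np.sqrt(1.0 - c_star**2) * rng.standard_normal(n)
        proj = pts @ d
        reordered = np.empty_like(pts)
        reordered[np.argsort(u)] = pts[np.argsort(proj)]
        pts = reordered

    out = truth[["neuron_id"]].copy()
    out[["x_mm", "y_mm", "z_mm"]] = pts
    return out


def generate_dataset(config: SimConfig) -> Dataset:
    """Run all four generators off independent streams of the master seed."""
    config.validate()
    streams = _rng_streams(config.seed)
    trials = simulate_trials(config, rng=streams["trials"])
    spikes, truth = simulate_spikes(config, trials, rng=streams["spikes"])
    eye = simulate_eye(trials, config, rng=streams["eye"])
    anatomy = assign_anatomy(config, truth, rng=streams["anatomy"])
    truth = truth.merge(anatomy, on="neuron_id")
    params = {
        "k_true": config.k_true,
        "a_true": config.a_true,
        "gradient_direction": list(np.asarray(config.gradient_direction)
                                   / np.linalg.norm(config.gradient_direction)),
        "gradient_strength": config.gradient_strength,
        "encoding_gain": config.encoding_gain,
        "seed": config.seed,
    }
    return Dataset(config=config, trials=trials, spikes=spikes, truth=truth,
                   eye=eye, truth_params=params)
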