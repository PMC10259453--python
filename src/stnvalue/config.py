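"""Configuration objects for simulation and pipeline runs."""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field


class ConfigError(ValueError):
    """Raised when a configuration is internally inconsistent."""


#: Canonical encoding patterns in the (beta_R, beta_D) plane, plus the
#: switcher (Discounting- in phase 1 -> Compounding+ in phase 2) and
#: untuned (no condition coding at all).
CATEGORIES = (
    "Discounting-",
    "Discounting+",
    "Compounding+",
    "Compounding-",
    "switcher",
    "untuned",
)

DEFAULT_CATEGORY_MIX = {
    "Discounting-": 0.20,
    "Discounting+": 0.08,
    "Compounding+": 0.10,
    "Compounding-": 0.06,
    "switcher": 0.10,
    "untuned": 0.46,
}


@dataclass
class SimConfig:
    """Ground-truth generator settings.

    Defaults emulate the study conditions of the source recordings: a 3x2
    reward (1-3 drops) by delay (short 3.5-5.6 s / long 5.2-7.3 s) design,
    hyperbolic-discounting rejection behavior, cue-locked transients with
    phase-dependent reward/delay gain modulation, eye-position nuisance
    signals, and a dorso-posterior gradient of encoding strength.
    """

    n_sessions: int = 30
    trials_per_session: int = 180
    reward_levels: tuple = (1, 2, 3)
    delay_short_range_s: tuple = (3.5, 5.6)
    delay_long_range_s: tuple = (5.2, 7.3)
    k_true: float = 1.62        # discount factor, 1/s
    a_true: float = 40.0        # behavioral scale of the rejection model
    n_neurons: int = 231
    category_mix: dict = field(default_factory=lambda: dict(DEFAULT_CATEGORY_MIX))
    baseline_rate_range_hz: tuple = (5.0, 30.0)
    encoding_gain: float = 0.3          # log-rate units
    interaction_gain: float = 0.0       # log-rate units for w_RD
    gradient_direction: tuple = (0.0, -0.7071067811865476, 0.7071067811865476)
    gradient_strength: float = 0.35     # target Spearman rho
    seed: int = 0

    # spike-train construction
    spike_t_start_s: float = -1.2
    spike_t_stop_s: float = 3.7
    transient_amp: float = 0.8          # log-rate units of the cue bump
    transient_peak_s: float = 0.15
    transient_sd_s: float = 0.05
    switch_time_s: float = 2.0

    # eye-signal construction
    eye_rate_hz: float = 240.0
    eye_ar_coef: float = 0.95
    eye_noise_sd_deg: float = 0.5       # stationary sd of the AR(1) part
    eye_reward_gain_deg: float = 0.3    # post-cue offset per z(R)
    eye_delay_gain_deg: float = 0.2     # post-cue offset per z(D)
    eye_ramp_s: float = 0.3

    def validate(self) -> None:
        if self.n_sessions <= 0 or self.trials_per_session <= 0:
            raise ConfigError("n_sessions and trials_per_session must be positive")
        if self.n_neurons <= 0:
            raise ConfigError("n_neurons must be positive")
        if self.k_true < 0:
            raise ConfigError("k_true must be >= 0")
        if self.a_true <= 0:
            raise ConfigError("a_true must be > 0")
        for name in ("delay_short_range_s", "delay_long_range_s",
                     "baseline_rate_range_hz"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigError(f"{name}: lower bound exceeds upper bound")
        mix = self.category_mix
        unknown = set(mix) - set(CATEGORIES)
        if unknown:
            raise ConfigError(f"unknown categories in category_mix: {unknown}")
        total = sum(mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"category_mix proportions sum to {total}, not 1")
        if any(v < 0 for v in mix.values()):
            raise ConfigError("category_mix proportions must be nonnegative")
        if not 0.0 <= self.gradient_strength <= 1.0:
            raise ConfigError("gradient_strength must lie in [0, 1]")
        if self.trials_per_session % (2 * len(self.reward_levels)):
            raise ConfigError(
                "trials_per_session must be a multiple of the number of "
                "conditions for a balanced design")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["reward_levels"] = list(self.reward_levels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        kwargs = dict(d)
        for name in ("reward_levels", "delay_short_range_s",
                     "delay_long_range_s", "baseline_rate_range_hz",
                     "gradient_direction"):
            if name in kwargs:
                kwargs[name] = tuple(kwargs[name])
        return cls(**kwargs)


@dataclass
class PipelineConfig:
    """End-to-end run settings; serialized verbatim into the run report."""

    sim: SimConfig = field(default_factory=SimConfig)
    seed: int = 0
    window_width_s: float = 0.200
    window_step_s: float = 0.020
    phase1_bounds_s: tuple = (0.0, 2.0)
    phase2_bounds_s: tuple = (2.0, 3.5)
    alpha: float = 0.05
    bonferroni_n: int = 174
    bonferroni_n_continuous: int = 173
    n_shuffles: int = 200       # 1000 for the full-fidelity profile
    fit_n_starts: int = 10
    include_eye: bool = True
    delay_coding: str = "seconds"   # or "class"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = self.sim.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = dict(d)
        if "sim" in kwargs:
            kwargs["sim"] = SimConfig.from_dict(kwargs["sim"])
        for name in ("phase1_bounds_s", "phase2_bounds_s"):
            if name in kwargs:
                kwargs[name] = tuple(kwargs[name])
        return cls(**kwargs)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
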