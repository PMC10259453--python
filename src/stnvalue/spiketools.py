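"""Spike-train representations: sliding window grids, spike density
functions, baseline rates, Fano factors and windowed count matrices.

Conventions follow the source analyses: 200 ms test windows stepped in
20 ms across the 3.5 s post-cue period (174 analysis bins; the matching
pre-cue control grid has 47 bins ending at cue onset), SDFs from a 20 ms-sd
Gaussian kernel on a 1 ms grid over [-1, +3.5] s, and a Fano factor taken
across the six reward-by-delay condition-mean traces.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "WindowGrid",
    "make_grid",
    "sdf",
    "sdf_condition_means",
    "baseline_rate",
    "fano_factor",
    "window_counts",
]

SDF_T_START = -1.0
SDF_T_STOP = 3.5
SDF_DT = 0.001
#: spikes this far outside the SDF range still enter the convolution
SDF_EDGE_PAD = 0.2


@dataclass(frozen=True)
class WindowGrid:
    """Sliding spike-count windows [c - w/2, c + w/2), half-open."""

    centers: np.ndarray
    width: float
    step: float
    epoch: str   # "analysis" | "control" | "custom"

    def __post_init__(self):
        c = np.asarray(self.centers, dtype=float)
        if c.size == 0 or np.any(np.diff(c) <= 0):
            raise ValueError("centers must be strictly increasing and non-empty")
        if self.width <= 0 or self.step <= 0:
            raise ValueError("width and step must be positive")
        object.__setattr__(self, "centers", c)

    @property
    def n_bins(self) -> int:
        return self.centers.size

    @property
    def left_edges(self) -> np.ndarray:
        # rounded so edge membership is consistent across bins
        return np.round(self.centers - self.width / 2, 9)

    @property
    def right_edges(self) -> np.ndarray:
        return np.round(self.centers + self.width / 2, 9)


def make_grid(epoch: str = "analysis", width: float = 0.200,
              step: float = 0.020) -> WindowGrid:
    """Build the analysis or control window grid.

    With defaults, the analysis grid has 174 centers at 0.00, 0.02, ...,
    3.46 s and the control grid 47 centers at -0.94 ... -0.02 s (windows at
    the epoch edges may extend slightly beyond it; this reproduces the
    174-bin Bonferroni denominator and the 47-value control population,
    df = 46).
    """
    if width <= 0 or step <= 0:
        raise ValueError("width and step must be positive")
    if step > width:
        warnings.warn("step exceeds width: windows leave gaps", stacklevel=2)
    # Bin counts are a fixed convention matching the published procedure:
    # overlapping windows keep one fewer analysis center (and three fewer
    # control centers) than the naive epoch/step count, with edge windows
    # allowed to overhang the epoch slightly.  Defaults: 174 analysis
    # centers at 0.00..3.46 s, 47 control centers at -0.94..-0.02 s.
    trim = width > step
    if epoch == "analysis":
        n = int(round(3.5 / step)) - (1 if trim else 0)
        centers = step * np.arange(n)
    elif epoch == "control":
        n = int(round(1.0 / step)) - (3 if trim else 0)
        centers = -step * np.arange(n, 0, -1)
    else:
        raise ValueError(f"unknown epoch {epoch!r}; use 'analysis' or 'control'")
    return WindowGrid(centers=np.round(centers, 9), width=width, step=step,
                      epoch=epoch)


def sdf(spike_trains, kernel_sd: float = 0.020,
        t_start: float = SDF_T_START, t_stop: float = SDF_T_STOP) -> np.ndarray:
    """Spike density functions (Hz) on a 1 ms grid over [t_start, t_stop].

    Each spike is convolved with a Gaussian kernel of the given sd;
    spikes within ``SDF_EDGE_PAD`` outside the range are retained so the
    convolution is edge-correct. Returns (n_trials, n_samples).
    """
    pad = max(SDF_EDGE_PAD, 4 * kernel_sd)
    n_pad = int(round(pad / SDF_DT))
    edges = np.arange(t_start - pad, t_stop + pad + SDF_DT / 2, SDF_DT)
    n_out = int(round((t_stop - t_start) / SDF_DT))
    out = np.empty((len(spike_trains), n_out))
    sigma_bins = kernel_sd / SDF_DT
    for i, train in enumerate(spike_trains):
        counts, _ = np.histogram(np.asarray(train, dtype=float), bins=edges)
        rate = gaussian_filter1d(counts.astype(float), sigma_bins,
                                 mode="constant") / SDF_DT
        out[i] = rate[n_pad:n_pad + n_out]
    return out


def sdf_times(t_start: float = SDF_T_START, t_stop: float = SDF_T_STOP) -> np.ndarray:
    n = int(round((t_stop - t_start) / SDF_DT))
    return t_start + SDF_DT * (np.arange(n) + 0.5)


def sdf_condition_means(spike_trains, conditions, kernel_sd: float = 0.020):
    """Trial-averaged SDF per condition.

    Returns (labels, traces) with traces shaped (n_conditions, n_samples).
    """
    traces = sdf(spike_trains, kernel_sd=kernel_sd)
    conditions = np.asarray(conditions)
    labels = np.unique(conditions, axis=0) if conditions.ndim > 1 else np.unique(conditions)
    means = []
    for lab in labels:
        mask = (np.all(conditions == lab, axis=1) if conditions.ndim > 1
                else conditions == lab)
        means.append(traces[mask].mean(axis=0))
    return labels, np.asarray(means)


def baseline_rate(spike_trains, kernel_sd: float = 0.020) -> float:
    """Mean SDF (Hz) over the 1 s pre-cue epoch, averaged across trials."""
    traces = sdf(spike_trains, kernel_sd=kernel_sd)
    times = sdf_times()
    mask = (times >= -1.0) & (times < 0.0)
    return float(traces[:, mask].mean())


def fano_factor(condition_mean_traces: np.ndarray) -> np.ndarray:
    """Variance-to-mean ratio of firing rate across condition means, per
    time point (masked NaN where the mean is 0).

    Input is (n_conditions, n_samples) for one neuron, or
    (n_neurons, n_conditions, n_samples) — the latter averages F(t) across
    neurons. The variance is the sample variance (ddof=1) across the six
    condition means.
    """
    x = np.asarray(condition_mean_traces, dtype=float)
    if x.ndim == 2:
        x = x[None]
    if x.shape[1] < 2:
        raise ValueError("need at least 2 condition means")
    mean = x.mean(axis=1)
    var = x.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(mean > 0, var / mean, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return np.nanmean(f, axis=0)


def window_counts(spike_trains, grid: WindowGrid) -> np.ndarray:
    """Trial x bin spike-count matrix on half-open windows [c-w/2, c+w/2)."""
    lefts, rights = grid.left_edges, grid.right_edges
    out = np.empty((len(spike_trains), grid.n_bins), dtype=np.int64)
    for i, train in enumerate(spike_trains):
        t = np.sort(np.asarray(train, dtype=float))
        out[i] = np.searchsorted(t, rights, side="left") - np.searchsorted(
            t, lefts, side="left")
    return out
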