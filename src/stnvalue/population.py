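"""Population PCA on the neurons x (coefficients x time-bins) beta matrix.

Each neuron contributes its time series of standardized reward and delay
coefficients, refit on non-overlapping 100 ms windows (35 bins over
0-3.5 s) so betas are independent across bins. The matrix (all beta_R
bins, then all beta_D bins) is column-centered and eigendecomposed;
eigenvectors are read per bin as (beta_R, beta_D) vectors in the
reward/delay subspace, giving per-PC angle/magnitude trajectories.
Significance comes from trial-shuffle surrogates: per shuffle every
neuron's trial labels are permuted (whole trials, jointly across bins),
the regressions refit, and the PCA re-run; the 2.5-97.5 percentile
envelopes of explained variance and per-bin eigenvector magnitude are the
significance bounds.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import zscore_columns
from .encoding import RegressorSet, window_average, fit_betas
from .spiketools import WindowGrid, window_counts
from .vectors import encoding_angle

logger = logging.getLogger(__name__)

__all__ = [
    "pca_grid",
    "BetaMatrix",
    "PCAResults",
    "SurrogateEnvelope",
    "build_beta_matrix",
    "run_pca",
    "surrogate_envelope",
    "significant_pcs",
    "PopulationPCA",
]

MIN_TRIALS = 20


def pca_grid(width: float = 0.100) -> WindowGrid:
    """Non-overlapping window grid for the population matrix (T=35 bins of
    100 ms over 0-3.5 s by default)."""
    n = int(round(3.5 / width))
    centers = width / 2 + width * np.arange(n)
    return WindowGrid(centers=centers, width=width, step=width, epoch="custom")


@dataclass
class BetaMatrix:
    """Neurons x (2 x T) matrix of reward/delay betas.

    Column order is fixed: all beta_R bins (ascending time), then all
    beta_D bins.
    """

    values: np.ndarray
    neuron_ids: np.ndarray
    centers: np.ndarray

    @property
    def n_bins(self) -> int:
        return self.centers.size

    def to_frame(self) -> pd.DataFrame:
        cols = ([f"beta_R_{c:.3f}" for c in self.centers]
                + [f"beta_D_{c:.3f}" for c in self.centers])
        df = pd.DataFrame(self.values, columns=cols)
        df.insert(0, "neuron_id", self.neuron_ids)
        return df


def _neuron_betas(counts: np.ndarray, reg: RegressorSet,
                  grid: WindowGrid) -> np.ndarray:
    """(beta_R series, beta_D series) for one neuron on the PCA grid."""
    series = fit_betas(counts, reg, grid)
    iR, iD = series.names.index("reward"), series.names.index("delay")
    return np.concatenate([series.betas[:, iR], series.betas[:, iD]])


def build_beta_matrix(spike_trains_by_neuron, regressors_by_neuron,
                      neuron_ids=None, grid: WindowGrid | None = None) -> BetaMatrix:
    """Refit the per-bin regression on the non-overlapping grid for every
    recorded neuron (tuned or not) and assemble the population matrix.

    Neurons with fewer than 20 completed trials are excluded (logged);
    undefined betas are set to 0 with a logged count.
    """
    if grid is None:
        grid = pca_grid()
    if neuron_ids is None:
        neuron_ids = np.arange(len(spike_trains_by_neuron))
    rows, kept, n_nan = [], [], 0
    for nid, trains, reg in zip(neuron_ids, spike_trains_by_neuron,
                                regressors_by_neuron):
        if len(trains) < MIN_TRIALS:
            logger.warning("build_beta_matrix: neuron %s excluded "
                           "(%d trials < %d)", nid, len(trains), MIN_TRIALS)
            continue
        counts = window_counts(trains, grid)
        row = _neuron_betas(counts, reg, grid)
        bad = ~np.isfinite(row)
        n_nan += int(bad.sum())
        row[bad] = 0.0
        rows.append(row)
        kept.append(nid)
    if n_nan:
        logger.info("build_beta_matrix: %d undefined betas set to 0", n_nan)
    if not rows:
        raise ValueError("no neuron had enough trials")
    return BetaMatrix(values=np.asarray(rows), neuron_ids=np.asarray(kept),
                      centers=grid.centers)


@dataclass
class PCAResults:
    """Eigendecomposition of the column covariance of the beta matrix."""

    components: np.ndarray              # (n_pc, 2*T) orthonormal rows
    explained_variance_pct: np.ndarray  # sums to 100 over all PCs
    scores: np.ndarray                  # (n_neurons, n_pc)
    neuron_ids: np.ndarray
    centers: np.ndarray

    @property
    def n_pcs(self) -> int:
        return self.components.shape[0]

    def eigenvector_series(self, pc_index: int) -> pd.DataFrame:
        """Per-bin (beta_R, beta_D) components, angle (deg) and magnitude of
        one eigenvector."""
        if not 0 <= pc_index < self.n_pcs:
            raise IndexError(f"pc_index {pc_index} out of range")
        T = self.centers.size
        v = self.components[pc_index]
        vR, vD = v[:T], v[T:]
        mag = np.hypot(vR, vD)
        theta = np.array([encoding_angle(r, d) if m > 0 else np.nan
                          for r, d, m in zip(vR, vD, mag)])
        return pd.DataFrame({"bin_center_s": self.centers, "beta_R_comp": vR,
                             "beta_D_comp": vD, "theta_deg": theta,
                             "magnitude": mag})

    def summary(self, n_show: int = 4) -> str:
        lines = ["Population PCA", "-" * 40]
        for i in range(min(n_show, self.n_pcs)):
            lines.append(
                f"PC{i + 1}: {self.explained_variance_pct[i]:5.1f}% variance")
        lines.append(
            f"first {min(n_show, self.n_pcs)} PCs: "
            f"{self.explained_variance_pct[:n_show].sum():.1f}% of variance")
        return "\n".join(lines)


def _orient(components: np.ndarray, T: int) -> np.ndarray:
    """Deterministic eigenvector orientation: net beta_R component >= 0
    (fallback: largest-magnitude element positive)."""
    out = components.copy()
    for i, v in enumerate(out):
        s = v[:T].sum()
        if abs(s) > 1e-12:
            if s < 0:
                out[i] = -v
        elif v[np.argmax(np.abs(v))] < 0:
            out[i] = -v
    return out


def run_pca(matrix: BetaMatrix) -> PCAResults:
    """PCA of the column-centered (not variance-scaled) beta matrix."""
    X = matrix.values - matrix.values.mean(axis=0, keepdims=True)
    total = float(np.sum(X * X))
    if total <= 0:
        raise ValueError("beta matrix has zero variance")
    n = X.shape[0]
    cov = (X.T @ X) / (n - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order], 0.0)
    comps = _orient(evecs[:, order].T, matrix.n_bins)
    pct = 100.0 * evals / evals.sum()
    scores = X @ comps.T
    return PCAResults(components=comps, explained_variance_pct=pct,
                      scores=scores, neuron_ids=matrix.neuron_ids,
                      centers=matrix.centers)


@dataclass
class SurrogateEnvelope:
    """95% percentile envelopes of explained variance and eigenvector
    magnitude under trial shuffling."""

    variance_lo: np.ndarray             # (n_pc,) 2.5th percentile
    variance_hi: np.ndarray             # 97.5th
    magnitude_lo: np.ndarray            # (n_pc, T)
    magnitude_hi: np.ndarray
    n_shuffles: int
    seed: int


def _fast_betas_factory(spike_trains, reg: RegressorSet, grid: WindowGrid):
    """Precompute per-bin design pseudoinverses and z-scored counts for one
    neuron so shuffled refits are two einsums.

    Returns (refit(perm) -> concatenated beta_R/beta_D row).
    """
    ycols = window_counts(spike_trains, grid).astype(float)
    nb = grid.n_bins
    n = ycols.shape[0]
    zr = zscore_columns(reg.reward)[0]
    zd = zscore_columns(reg.delay)[0]
    cols = [np.ones((n, nb)), np.broadcast_to(zr[:, None], (n, nb)),
            np.broadcast_to(zd[:, None], (n, nb))]
    if reg.has_eye:
        for trace in (reg.eye_pos, reg.eye_vel):
            m = window_average(trace, reg.eye_times, grid)
            cols.append(zscore_columns(m)[0])
    k = len(cols)
    pinvs = np.empty((nb, k, n))
    for b in range(nb):
        X = np.column_stack([c[:, b] for c in cols])
        pinvs[b] = np.linalg.pinv(X)

    def refit(perm=None):
        y = ycols if perm is None else ycols[perm]
        betas = np.einsum("bkt,tb->bk", pinvs, y)
        return np.concatenate([betas[:, 1], betas[:, 2]])

    return refit


def surrogate_envelope(spike_trains_by_neuron, regressors_by_neuron,
                       n_shuffles: int = 1000, seed: int = 0,
                       grid: WindowGrid | None = None,
                       n_pcs: int | None = None) -> SurrogateEnvelope:
    """Trial-shuffle surrogate distribution of the population PCA.

    Per shuffle, each neuron's per-trial counts are permuted across trials
    (jointly across bins, independently across neurons), the per-bin
    regression is refit, the matrix rebuilt, and the PCA re-run; surrogate
    PCs are matched to real PCs by rank.
    """
    if n_shuffles < 100:
        logger.warning("surrogate_envelope: n_shuffles=%d < 100 gives "
                       "unstable 95%% bounds", n_shuffles)
    if grid is None:
        grid = pca_grid()
    rng = np.random.default_rng(seed)
    refits, n_trials = [], []
    for trains, reg in zip(spike_trains_by_neuron, regressors_by_neuron):
        if len(trains) < MIN_TRIALS:
            continue
        refits.append(_fast_betas_factory(trains, reg, grid))
        n_trials.append(len(trains))
    T = grid.n_bins
    n_cols = 2 * T
    if n_pcs is None:
        n_pcs = n_cols
    var_samples = np.empty((n_shuffles, n_pcs))
    mag_samples = np.empty((n_shuffles, n_pcs, T))
    for s in range(n_shuffles):
        rows = [refit(rng.permutation(nt))
                for refit, nt in zip(refits, n_trials)]
        mat = BetaMatrix(values=np.nan_to_num(np.asarray(rows)),
                         neuron_ids=np.arange(len(rows)), centers=grid.centers)
        res = run_pca(mat)
        var_samples[s] = res.explained_variance_pct[:n_pcs]
        comps = res.components[:n_pcs]
        mag_samples[s] = np.hypot(comps[:, :T], comps[:, T:])
    return SurrogateEnvelope(
        variance_lo=np.percentile(var_samples, 2.5, axis=0),
        variance_hi=np.percentile(var_samples, 97.5, axis=0),
        magnitude_lo=np.percentile(mag_samples, 2.5, axis=0),
        magnitude_hi=np.percentile(mag_samples, 97.5, axis=0),
        n_shuffles=n_shuffles, seed=seed)


def significant_pcs(result: PCAResults, envelope: SurrogateEnvelope):
    """PCs whose explained variance falls outside the surrogate 95%
    interval, plus per-bin significant-magnitude masks (same rule)."""
    n = envelope.variance_lo.size
    var = result.explained_variance_pct[:n]
    sig = np.flatnonzero((var < envelope.variance_lo)
                         | (var > envelope.variance_hi))
    T = result.centers.size
    comps = result.components[:n]
    mags = np.hypot(comps[:, :T], comps[:, T:])
    masks = (mags < envelope.magnitude_lo) | (mags > envelope.magnitude_hi)
    return sig.tolist(), masks


class PopulationPCA:
    """Model object: population PCA of per-neuron beta series.

    Build from a ready ``BetaMatrix`` or from per-neuron spikes/regressors
    via :meth:`from_neurons`; ``fit`` returns :class:`PCAResults`.
    """

    def __init__(self, matrix: BetaMatrix):
        self.matrix = matrix

    @classmethod
    def from_neurons(cls, spike_trains_by_neuron, regressors_by_neuron,
                     neuron_ids=None, grid: WindowGrid | None = None):
        return cls(build_beta_matrix(spike_trains_by_neuron,
                                     regressors_by_neuron, neuron_ids, grid))

    def fit(self) -> PCAResults:
        return run_pca(self.matrix)
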