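"""Encoding-vector taxonomy in the reward x delay regression subspace.

Significant (beta_R, beta_D) pairs form per-bin vectors originating at the
pre-cue control mean; their phase-wise resultants are classified by angle:
Discounting- (-90..0 deg, reward+ / delay-), Discounting+ (90..180),
Compounding+ (0..90), Compounding- (-180..-90). Population-level circular
statistics (Rayleigh test on the angle distribution, chi-square on category
counts, one-way ANOVA on magnitudes) and anatomical category contrasts
complete the taxonomy.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import rayleigh_test
from .encoding import BetaSeries

__all__ = [
    "EncodingVector",
    "encoding_angle",
    "classify_angle",
    "vector_series",
    "phase_sum",
    "standardize_vector",
    "population_stats",
    "position_contrast",
    "PHASE1_BOUNDS",
    "PHASE2_BOUNDS",
]

PHASE1_BOUNDS = (0.0, 2.0)
PHASE2_BOUNDS = (2.0, 3.5)

CATEGORY_LABELS = ("Discounting-", "Discounting+", "Compounding+", "Compounding-")


@dataclass
class EncodingVector:
    """Resultant encoding vector for one neuron and phase."""

    theta: float                # degrees in (-180, 180]
    magnitude: float            # standardized beta units
    phase: int                  # 1 or 2
    n_significant_bins: int
    components: tuple = (0.0, 0.0)      # (beta_R, beta_D) resultant

    @property
    def category(self) -> str:
        if self.n_significant_bins == 0 or self.magnitude == 0.0:
            return "unclassified"
        return classify_angle(self.theta)


def encoding_angle(beta_R: float, beta_D: float) -> float:
    """Four-quadrant arctangent angle (degrees, (-180, 180]) of a
    (beta_R, beta_D) pair: 0 deg = pure positive reward coding, 90 deg =
    pure positive delay coding."""
    theta = float(np.degrees(np.arctan2(beta_D, beta_R)))
    if theta <= -180.0:
        theta = 180.0
    return theta


def classify_angle(theta: float) -> str:
    """Category of an encoding angle.

    (-90, 0) Discounting-; (0, 90) Compounding+; (90, 180) Discounting+;
    (-180, -90) Compounding-. Exact boundaries are assigned
    counter-clockwise: 0 -> Compounding+, 90 -> Discounting+,
    -90 -> Discounting-, 180 -> Discounting+.
    """
    if not -180.0 < theta <= 180.0:
        raise ValueError("theta must lie in (-180, 180]")
    if -90.0 <= theta < 0.0:
        return "Discounting-"
    if 0.0 <= theta < 90.0:
        return "Compounding+"
    if 90.0 <= theta <= 180.0:
        return "Discounting+"
    return "Compounding-"


def vector_series(series: BetaSeries) -> pd.DataFrame:
    """Per-bin (beta_R, beta_D) vectors for bins where either coefficient
    is flagged significant, with origin at the control-epoch mean pair.

    Returns a DataFrame (bin_center_s, v_R, v_D) — empty if nothing is
    significant.
    """
    if series.sig is None:
        raise ValueError("run beta_significance first")
    iR, iD = series.names.index("reward"), series.names.index("delay")
    keep = series.sig[:, iR] | series.sig[:, iD]
    origin_R, origin_D = series.control_mean[iR], series.control_mean[iD]
    return pd.DataFrame({
        "bin_center_s": series.centers[keep],
        "v_R": series.betas[keep, iR] - origin_R,
        "v_D": series.betas[keep, iD] - origin_D,
    })


def phase_sum(vectors: pd.DataFrame, phase_window, phase: int = 1) -> EncodingVector:
    """Component-wise resultant of in-window vectors (membership by bin
    center; [lo, hi) except the final phase, which closes at 3.5 s)."""
    lo, hi = phase_window
    closed = hi >= PHASE2_BOUNDS[1]
    c = vectors["bin_center_s"].to_numpy() if len(vectors) else np.empty(0)
    mask = (c >= lo) & ((c <= hi) if closed else (c < hi))
    n = int(mask.sum())
    if n == 0:
        return EncodingVector(theta=np.nan, magnitude=0.0, phase=phase,
                              n_significant_bins=0)
    vR = float(vectors["v_R"].to_numpy()[mask].sum())
    vD = float(vectors["v_D"].to_numpy()[mask].sum())
    mag = float(np.hypot(vR, vD))
    theta = encoding_angle(vR, vD) if mag > 0 else np.nan
    return EncodingVector(theta=theta, magnitude=mag, phase=phase,
                          n_significant_bins=n, components=(vR, vD))


def standardize_vector(vector: EncodingVector, control_mean,
                       control_sd) -> EncodingVector:
    """Calibrate a vector for population figures: each component maps to
    (beta - control_mean) / (2 * control_sd). Zero-sd components are left
    unscaled (flagged via unchanged magnitude)."""
    comp = np.asarray(vector.components, dtype=float)
    mean = np.asarray(control_mean, dtype=float)
    sd = np.asarray(control_sd, dtype=float)
    scale = np.where(sd > 0, 2.0 * sd, 1.0)
    newc = (comp - mean) / scale
    mag = float(np.hypot(*newc))
    theta = encoding_angle(*newc) if mag > 0 else np.nan
    return EncodingVector(theta=theta, magnitude=mag, phase=vector.phase,
                          n_significant_bins=vector.n_significant_bins,
                          components=tuple(newc))


def population_stats(vectors) -> dict:
    """Population summary of classified encoding vectors.

    Returns the population resultant (vector sum of the supplied vectors),
    the Rayleigh test of angular uniformity (z = n*Rbar^2), a chi-square
    goodness-of-fit of the 4 category counts against uniform (df = 3,
    unclassified vectors excluded), and a one-way ANOVA of vector
    magnitudes across categories.
    """
    vecs = [v for v in vectors if v.n_significant_bins > 0 and v.magnitude > 0]
    if len(vecs) < 8:
        raise ValueError("need >= 8 classified vectors")
    comps = np.array([v.components for v in vecs])
    angles = np.array([v.theta for v in vecs])
    mags = np.array([v.magnitude for v in vecs])
    cats = np.array([v.category for v in vecs])

    pop = comps.sum(axis=0)
    pop_theta = encoding_angle(*pop)
    z, p_ray, mean_angle, rbar = rayleigh_test(angles)

    counts = np.array([(cats == c).sum() for c in CATEGORY_LABELS])
    chi2, p_chi2 = stats.chisquare(counts)

    groups = [mags[cats == c] for c in CATEGORY_LABELS if (cats == c).sum() > 0]
    if len(groups) >= 2:
        F, p_anova = stats.f_oneway(*groups)
        df_anova = (len(groups) - 1, int(sum(len(g) for g in groups)) - len(groups))
    else:
        F, p_anova, df_anova = np.nan, np.nan, (0, 0)

    return {
        "n": len(vecs),
        "population_vector": {"theta": pop_theta,
                              "magnitude": float(np.hypot(*pop)),
                              "components": pop.tolist()},
        "rayleigh": {"z": z, "p": p_ray, "mean_angle": mean_angle,
                     "rbar": rbar},
        "category_counts": dict(zip(CATEGORY_LABELS, counts.tolist())),
        "chi2": {"chi2": float(chi2), "df": len(CATEGORY_LABELS) - 1,
                 "p": float(p_chi2)},
        "magnitude_anova": {"F": float(F), "df": df_anova, "p": float(p_anova)},
    }


def position_contrast(labels, features: pd.DataFrame, target: str) -> dict:
    """Pooled-variance two-sample t of the target category against all
    other neurons, per coordinate axis / scalar feature column.

    df = n1 + n2 - 2 (e.g. 229 for 231 neurons).
    """
    labels = np.asarray(labels)
    in_grp = labels == target
    if in_grp.sum() < 2 or (~in_grp).sum() < 2:
        raise ValueError("need >= 2 neurons per group")
    out = {}
    for col in features.columns:
        x = features[col].to_numpy(dtype=float)
        a, b = x[in_grp], x[~in_grp]
        t, p = stats.ttest_ind(a, b, equal_var=True)
        out[col] = {"t": float(t), "p": float(p),
                    "df": a.size + b.size - 2,
                    "mean_in": float(a.mean()), "mean_out": float(b.mean())}
    return out
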