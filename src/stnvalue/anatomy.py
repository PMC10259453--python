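"""Anatomical gradient scan: rank correlations between per-neuron scores
and position projected onto a rotated set of anatomical axes.

The axis set for 45-degree rotations is the integer-lattice direction set
(all nonzero vectors with components in {-1, 0, 1}, normalized, antiparallel
pairs collapsed -> 13 unique directions); each reported axis is oriented so
that the correlation is nonnegative.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["AxisScan", "axis_directions", "gradient_scan"]


@dataclass
class AxisScan:
    """Per-direction Spearman rho/p and the best (max |rho|) axis."""

    table: pd.DataFrame          # dx, dy, dz, rho, p_raw[, p_perm]
    best_direction: np.ndarray
    best_rho: float
    best_p: float
    p_family: float | None = None   # permutation family-wise p of max |rho|


def axis_directions(step_deg: float = 45.0) -> np.ndarray:
    """Unit direction set for the rotated-axis scan.

    step 90 -> the 3 cardinal axes; step 45 -> the 13 integer-lattice
    directions (components in {-1, 0, 1}, sign-collapsed). Other steps have
    no defined direction set and raise.
    """
    if 90.0 % step_deg:
        raise ValueError("step_deg must divide 90")
    if step_deg == 90.0:
        return np.eye(3)
    if step_deg != 45.0:
        raise ValueError("only 45- and 90-degree steps are defined")
    dirs = []
    for x in (-1, 0, 1):
        for y in (-1, 0, 1):
            for z in (-1, 0, 1):
                v = np.array([x, y, z], dtype=float)
                if not v.any():
                    continue
                # collapse antiparallel duplicates: keep first nonzero > 0
                first = v[np.flatnonzero(v)[0]]
                if first < 0:
                    continue
                dirs.append(v / np.linalg.norm(v))
    return np.asarray(dirs)


def gradient_scan(scores, positions, step_deg: float = 45.0,
                  n_perm: int = 0, seed: int = 0) -> AxisScan:
    """Scan rotated anatomical axes for the strongest score gradient.

    For each direction, Spearman rho between the per-neuron score and the
    scalar projection of its (x, y, z) position; the best axis maximizes
    |rho| and is reported with orientation flipped so rho >= 0. p per axis
    is the standard t approximation; with ``n_perm`` > 0 a permutation
    family-wise p of max |rho| (positions shuffled jointly) is added.
    """
    scores = np.asarray(scores, dtype=float)
    pos = np.asarray(positions, dtype=float)
    if scores.size < 10:
        raise ValueError("need >= 10 neurons with coordinates")
    if pos.shape != (scores.size, 3):
        raise ValueError("positions must be (n, 3)")
    if np.all(pos == pos[0]):
        raise ValueError("all positions identical: rho undefined")
    dirs = axis_directions(step_deg)
    projs = pos @ dirs.T
    rows = []
    for j, d in enumerate(dirs):
        rho, p = stats.spearmanr(projs[:, j], scores)
        rows.append((d[0], d[1], d[2], float(rho), float(p)))
    table = pd.DataFrame(rows, columns=["dx", "dy", "dz", "rho", "p_raw"])
    best = int(table["rho"].abs().idxmax())
    best_rho = float(table.loc[best, "rho"])
    best_dir = dirs[best].copy()
    if best_rho < 0:
        best_dir, best_rho = -best_dir, -best_rho
    p_family = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        obs = float(table["rho"].abs().max())
        score_ranks = stats.rankdata(scores)
        proj_ranks = np.apply_along_axis(stats.rankdata, 0, projs)
        n = scores.size
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            pr = proj_ranks[perm]
            rho_all = np.abs(np.corrcoef(
                np.column_stack([score_ranks, pr]).T)[0, 1:])
            if rho_all.max() >= obs:
                exceed += 1
        p_family = (exceed + 1) / (n_perm + 1)
    return AxisScan(table=table, best_direction=best_dir, best_rho=best_rho,
                    best_p=float(table.loc[best, "p_raw"]),
                    p_family=p_family)
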