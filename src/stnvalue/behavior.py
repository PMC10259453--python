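"""Rejection-rate statistics and hyperbolic discounting fits.

The subjective value of a delayed reward is modeled hyperbolically,
SV = R / (1 + kD), and the willingness to wait is read out through the
rejection rate, modeled as E = (1 + kD) / (aR): rejections rise as
subjective value falls. ``HyperbolicDiscounting`` is the model object;
``fit`` performs a derivative-free simplex search (on log k, log a, so the
constraints k >= 0, a > 0 hold by construction) with multiple restarts and
returns a ``DiscountingResults`` carrying the estimates, R^2 and residuals.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._stats import two_way_anova

logger = logging.getLogger(__name__)

__all__ = [
    "subjective_value",
    "rejection_table",
    "condition_means",
    "anova_rejections",
    "HyperbolicDiscounting",
    "DiscountingResults",
    "fit_discounting",
    "choice_preference",
]


def subjective_value(R, D, k):
    """Temporally discounted value SV = R / (1 + k*D).

    Strictly decreasing in D for k > 0 and equal to R at D = 0.
    """
    R = np.asarray(R, dtype=float)
    D = np.asarray(D, dtype=float)
    if np.any(D < 0):
        raise ValueError("delay D must be nonnegative")
    if k < 0:
        raise ValueError("discount factor k must be nonnegative")
    out = R / (1.0 + k * D)
    return float(out) if out.ndim == 0 else out


def rejection_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Per session x condition rejection rates.

    E = rejected / total per cell; D = mean realized delay of the cell.
    Empty cells are flagged (E = NaN) and logged.
    """
    required = {"session_id", "reward_size", "delay_class", "delay_s", "outcome"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    grp = trials.groupby(["session_id", "reward_size", "delay_class"])
    tab = grp.agg(
        n_trials=("outcome", "size"),
        n_rejected=("outcome", lambda s: int((s == "rejected").sum())),
        D=("delay_s", "mean"),
    ).reset_index()
    tab["E"] = tab["n_rejected"] / tab["n_trials"]

    # flag sessions missing any of the 6 cells
    full = (trials["session_id"].nunique()
            * trials["reward_size"].nunique() * trials["delay_class"].nunique())
    if len(tab) < full:
        logger.warning("rejection_table: %d empty condition cells excluded",
                       full - len(tab))
    return tab.rename(columns={"reward_size": "R", "delay_class": "delay_class"})


def condition_means(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse a session-level rejection table to the 6 condition means."""
    return (table.groupby(["R", "delay_class"])
            .agg(D=("D", "mean"), E=("E", "mean"))
            .reset_index())


def anova_rejections(table: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Type-II two-way ANOVA (reward x delay, with interaction) on
    session-level rejection rates."""
    if table["session_id"].nunique() < 2:
        raise ValueError("need at least 2 sessions")
    for col in ("R", "delay_class"):
        if table[col].nunique() < 2:
            raise ValueError(f"factor {col} has a single level")
    res = two_way_anova(table["E"].to_numpy(),
                        table["R"].to_numpy(), table["delay_class"].to_numpy())
    out = {}
    for effect, (F, df1, df2, p) in res.items():
        out[effect] = {"F": F, "df": (df1, df2), "p": p,
                       "significant": bool(p < alpha) if np.isfinite(p) else False}
    return out


@dataclass
class DiscountingResults:
    """Fit of the hyperbolic rejection model E = (1 + kD)/(aR)."""

    k: float                    # discount factor, 1/s
    a: float                    # subject-specific scale
    r_squared: float
    n_starts_used: int
    sse: float
    table: pd.DataFrame         # condition means used (R, D, E, E_model)
    at_boundary: bool = False   # k driven to ~0 (no discounting detected)

    @property
    def params(self) -> np.ndarray:
        return np.array([self.k, self.a])

    def predict(self, R=None, D=None) -> np.ndarray:
        if R is None:
            R, D = self.table["R"].to_numpy(), self.table["D"].to_numpy()
        return (1.0 + self.k * np.asarray(D, dtype=float)) / (
            self.a * np.asarray(R, dtype=float))

    def subjective_value(self, R, D) -> np.ndarray:
        return subjective_value(R, D, self.k)

    def summary(self) -> str:
        lines = [
            "Hyperbolic discounting fit (E = (1 + kD) / (aR))",
            "-" * 48,
            f"k (discount factor)   {self.k:10.4f}  1/s",
            f"a (scale)             {self.a:10.4f}",
            f"R-squared             {self.r_squared:10.4f}",
            f"restarts used         {self.n_starts_used:10d}",
        ]
        if self.at_boundary:
            lines.append("note: k at lower boundary -- no measurable discounting")
        return "\n".join(lines)


class HyperbolicDiscounting:
    """Least-squares fit of condition-mean rejection rates to the
    hyperbolic rejection model.

    Parameters
    ----------
    table : DataFrame with columns R (drops), D (s), E (rejection rate).
        Usually the 6 condition means; a per-session table also works
        (each row is one residual).
    """

    def __init__(self, table: pd.DataFrame):
        table = table.dropna(subset=["E"])
        if table[["R", "D"]].drop_duplicates().shape[0] < 4:
            raise ValueError("need at least 4 distinct (R, D) cells")
        self.table = table.reset_index(drop=True)
        self._R = self.table["R"].to_numpy(dtype=float)
        self._D = self.table["D"].to_numpy(dtype=float)
        self._E = self.table["E"].to_numpy(dtype=float)

    @classmethod
    def from_trials(cls, trials: pd.DataFrame) -> "HyperbolicDiscounting":
        return cls(condition_means(rejection_table(trials)))

    #: search box for log k / log a; outside it the model is degenerate
    #: (k, a -> inf along a fixed ratio collapses E to (k/a) D/R)
    _LOG_BOUNDS = (np.log(1e-6), np.log(1e3))

    def _sse(self, log_params):
        k = np.exp(log_params[0])
        a = np.exp(log_params[1])
        pred = (1.0 + k * self._D) / (a * self._R)
        resid = self._E - pred
        sse = float(resid @ resid)
        lo, hi = self._LOG_BOUNDS
        for lp in log_params:
            sse += 1e3 * (max(0.0, lp - hi) ** 2 + max(0.0, lo - lp) ** 2)
        return sse

    def fit(self, n_starts: int = 10) -> DiscountingResults:
        if n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        k_starts = np.geomspace(0.01, 10.0, n_starts)
        best = None
        n_ok = 0
        for k0 in k_starts:
            # closed-form optimal 1/a given k makes the start well-scaled
            x = (1.0 + k0 * self._D) / self._R
            denom = float(x @ x)
            inv_a0 = float(x @ self._E) / denom if denom > 0 else 1.0
            a0 = 1.0 / max(inv_a0, 1e-8)
            res = optimize.minimize(
                self._sse, np.log([k0, a0]), method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 2000})
            if not np.all(np.isfinite(res.x)):
                continue
            n_ok += 1
            if best is None or res.fun < best.fun:
                best = res
        if best is None:
            raise RuntimeError(
                f"discounting fit failed to converge from all {n_starts} starts")
        k, a = np.exp(best.x)
        pred = (1.0 + k * self._D) / (a * self._R)
        sse = float(np.sum((self._E - pred) ** 2))
        sst = float(np.sum((self._E - self._E.mean()) ** 2))
        r2 = 1.0 - sse / sst if sst > 0 else np.nan
        at_boundary = k < 1e-4
        if at_boundary:
            logger.info("fit_discounting: k at lower boundary (%.2e)", k)
        tab = self.table.copy()
        tab["E_model"] = pred
        return DiscountingResults(k=float(k), a=float(a), r_squared=r2,
                                  n_starts_used=n_ok, sse=sse, table=tab,
                                  at_boundary=at_boundary)


def fit_discounting(table: pd.DataFrame, n_starts: int = 10) -> DiscountingResults:
    """Functional wrapper: fit condition means (R, D, E) and return results."""
    return HyperbolicDiscounting(table).fit(n_starts=n_starts)


def choice_preference(choice_trials: pd.DataFrame) -> dict:
    """Preference for the advantaged option in two-alternative choice trials.

    Each trial offers two options differing along exactly one dimension
    (reward with equal delay, or delay with equal reward). Returns, per
    dimension, the across-session mean fraction of advantaged choices and a
    one-sample t-test against 0.5 (df = sessions - 1). Rows whose options
    differ in both (or neither) dimension are rejected and logged.
    """
    req = {"session_id", "R1", "D1", "R2", "D2", "chosen"}
    missing = req - set(choice_trials.columns)
    if missing:
        raise ValueError(f"choice table missing columns: {sorted(missing)}")
    t = choice_trials.copy()
    diff_r = t["R1"] != t["R2"]
    diff_d = t["D1"] != t["D2"]
    bad = (diff_r & diff_d) | (~diff_r & ~diff_d)
    if bad.any():
        logger.warning("choice_preference: %d rows differ in both/neither "
                       "dimension; excluded", int(bad.sum()))
        t = t[~bad]
    out = {}
    for name, mask in (("reward", diff_r & ~bad), ("delay", diff_d & ~bad)):
        sub = t[mask.loc[t.index]]
        if sub.empty:
            out[name] = None
            continue
        if name == "reward":
            adv = np.where(sub["R1"] > sub["R2"], 1, 2)
        else:
            adv = np.where(sub["D1"] < sub["D2"], 1, 2)
        correct = (sub["chosen"].to_numpy() == adv).astype(float)
        per_session = (pd.Series(correct, index=sub["session_id"].to_numpy())
                       .groupby(level=0).mean())
        frac = float(per_session.mean())
        n = per_session.size
        if n > 1 and per_session.std(ddof=1) > 0:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                tt = stats.ttest_1samp(per_session, 0.5)
            t_stat, p = float(tt.statistic), float(tt.pvalue)
        else:
            t_stat, p = (np.inf, 0.0) if frac != 0.5 else (0.0, 1.0)
        out[name] = {"fraction": frac, "t": t_stat, "df": n - 1, "p": p,
                     "n_sessions": int(n)}
    return out
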