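"""Readers/writers for the pipeline's file contracts.

CSV: UTF-8, header row, '.' decimal. Dense eye arrays go to HDF5.
Round-trips are lossless to 1e-12.
"""
from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .synthetic import Dataset, EyeData, SpikeData

TRIALS_COLUMNS = ["session_id", "trial_id", "reward_size", "delay_class",
                  "delay_s", "outcome", "reject_time_s"]
SPIKES_COLUMNS = ["neuron_id", "session_id", "trial_id", "spike_time_s"]
NEURONS_COLUMNS = ["neuron_id", "x_mm", "y_mm", "z_mm", "baseline_hz",
                   "spike_width_ms", "spike_amp_uv"]

_FLOAT_FMT = "%.12g"


class SchemaError(ValueError):
    """A table does not match its expected column contract."""


def _check_schema(df: pd.DataFrame, expected, name: str,
                  allow_extra: bool = False) -> None:
    missing = [c for c in expected if c not in df.columns]
    extra = [c for c in df.columns if c not in expected]
    if missing or (extra and not allow_extra):
        raise SchemaError(
            f"{name}: missing columns {missing}, unexpected columns {extra}")


def write_trials(trials: pd.DataFrame, path) -> None:
    _check_schema(trials, TRIALS_COLUMNS, "trials", allow_extra=True)
    trials[TRIALS_COLUMNS].to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_schema(df, TRIALS_COLUMNS, "trials")
    bad = ~df["outcome"].isin(["completed", "rejected"])
    if bad.any():
        rows = df.index[bad].tolist()[:5]
        raise SchemaError(f"trials: malformed outcome values at rows {rows}")
    return df


def write_spikes(spikes: SpikeData, path) -> None:
    spikes.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_spikes(path, t_start: float = -1.2, t_stop: float = 3.7,
                trials: pd.DataFrame | None = None) -> SpikeData:
    df = pd.read_csv(path)
    _check_schema(df, SPIKES_COLUMNS, "spikes")
    neuron_ids = np.sort(df["neuron_id"].unique())
    session_of, trial_ids, spk = {}, {}, {}
    for nid, sub in df.groupby("neuron_id"):
        sid = int(sub["session_id"].iloc[0])
        session_of[int(nid)] = sid
        if trials is not None:
            tids = trials.loc[trials["session_id"] == sid, "trial_id"].to_numpy()
        else:
            tids = np.sort(sub["trial_id"].unique())
        by_trial = dict(tuple(sub.groupby("trial_id")))
        trains = []
        for tid in tids:
            grp = by_trial.get(tid)
            trains.append(np.sort(grp["spike_time_s"].to_numpy())
                          if grp is not None else np.empty(0))
        trial_ids[int(nid)] = tids
        spk[int(nid)] = trains
    return SpikeData(neuron_ids=neuron_ids, session_of=session_of,
                     trial_ids=trial_ids, spikes=spk,
                     t_start=t_start, t_stop=t_stop)


def write_neurons(truth: pd.DataFrame, path) -> None:
    _check_schema(truth, NEURONS_COLUMNS, "neurons", allow_extra=True)
    truth[NEURONS_COLUMNS].to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_neurons(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_schema(df, NEURONS_COLUMNS, "neurons")
    return df


def write_eye(eye: EyeData, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("times", data=eye.times)
        for sid, pos in eye.position.items():
            g = f.create_group(f"session_{sid}")
            g.create_dataset("position", data=pos, compression="gzip")
            g.create_dataset("velocity", data=eye.velocity[sid],
                             compression="gzip")


def read_eye(path) -> EyeData:
    eye = EyeData(times=None)
    with h5py.File(path, "r") as f:
        eye.times = f["times"][...]
        for key in f:
            if key.startswith("session_"):
                sid = int(key.split("_")[1])
                eye.position[sid] = f[key]["position"][...]
                eye.velocity[sid] = f[key]["velocity"][...]
    return eye


def write_truth(truth: pd.DataFrame, params: dict, path,
                config=None) -> None:
    payload = {"params": params,
               "neurons": truth.to_dict(orient="records")}
    if config is not None:
        payload["config"] = config.to_dict()
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth(path):
    payload = json.loads(Path(path).read_text())
    return pd.DataFrame(payload["neurons"]), payload["params"]


def load_dataset(data_dir) -> Dataset:
    """Reassemble a full Dataset from a directory written by
    :func:`write_dataset`."""
    from .config import SimConfig
    d = Path(data_dir)
    payload = json.loads((d / "truth.json").read_text())
    config = SimConfig.from_dict(payload.get("config", {}))
    truth = pd.DataFrame(payload["neurons"])
    trials = read_trials(d / "trials.csv")
    spikes = read_spikes(d / "spikes.csv", t_start=config.spike_t_start_s,
                         t_stop=config.spike_t_stop_s, trials=trials)
    eye = read_eye(d / "eye.h5")
    return Dataset(config=config, trials=trials, spikes=spikes, truth=truth,
                   eye=eye, truth_params=payload["params"])


def write_dataset(ds: Dataset, out_dir) -> dict:
    """Write all artifacts of a simulated dataset; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "trials": out / "trials.csv",
        "spikes": out / "spikes.csv",
        "neurons": out / "neurons.csv",
        "eye": out / "eye.h5",
        "truth": out / "truth.json",
    }
    write_trials(ds.trials, paths["trials"])
    write_spikes(ds.spikes, paths["spikes"])
    write_neurons(ds.truth, paths["neurons"])
    write_eye(ds.eye, paths["eye"])
    write_truth(ds.truth, ds.truth_params, paths["truth"], config=ds.config)
    return {k: str(v) for k, v in paths.items()}
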