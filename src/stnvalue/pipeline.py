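"""End-to-end orchestration: simulate -> behavior -> single-unit encoding
-> vector taxonomy -> population PCA -> anatomical gradient, with a
machine-readable run report."""
from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .behavior import HyperbolicDiscounting, anova_rejections, rejection_table
from .config import PipelineConfig
from .encoding import NeuronEncodingModel, RegressorSet
from .population import (PopulationPCA, pca_grid, significant_pcs,
                         surrogate_envelope)
from .anatomy import gradient_scan
from .synthetic import Dataset, generate_dataset
from .vectors import (phase_sum, population_stats, position_contrast,
                      standardize_vector, vector_series)
from . import io as stnio

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "neuron_inputs"]


def neuron_inputs(ds: Dataset, include_eye: bool = True,
                  delay_coding: str = "seconds"):
    """Per-neuron (spike trains, RegressorSet) over completed trials."""
    by_session = dict(tuple(ds.trials.groupby("session_id")))
    out = []
    for nid in ds.spikes.neuron_ids:
        nid = int(nid)
        sid = ds.spikes.session_of[nid]
        sess = by_session[sid].reset_index(drop=True)
        completed = (sess["outcome"] == "completed").to_numpy()
        trains = [t for t, ok in zip(ds.spikes.spikes[nid], completed) if ok]
        delay = (sess["delay_s"].to_numpy() if delay_coding == "seconds"
                 else (sess["delay_class"] == "long").to_numpy(dtype=float))
        kwargs = {}
        if include_eye:
            kwargs = {"eye_pos": ds.eye.position[sid][completed],
                      "eye_vel": ds.eye.velocity[sid][completed],
                      "eye_times": ds.eye.times}
        reg = RegressorSet(reward=sess["reward_size"].to_numpy()[completed],
                           delay=delay[completed],
                           delay_class=sess["delay_class"].to_numpy()[completed],
                           **kwargs)
        out.append((nid, trains, reg))
    return out


def _behavior_stage(ds: Dataset, cfg: PipelineConfig) -> dict:
    table = rejection_table(ds.trials)
    anova = anova_rejections(table, alpha=cfg.alpha)
    fit = HyperbolicDiscounting.from_trials(ds.trials).fit(
        n_starts=cfg.fit_n_starts)
    return {
        "k": fit.k, "a": fit.a, "r_squared": fit.r_squared,
        "k_true": ds.truth_params["k_true"],
        "anova": {e: {"F": float(v["F"]), "p": float(v["p"]),
                      "df": list(v["df"])} for e, v in anova.items()},
        "_fit": fit, "_table": table,
    }


def _encoding_stage(ds: Dataset, cfg: PipelineConfig) -> dict:
    inputs = neuron_inputs(ds, include_eye=cfg.include_eye,
                           delay_coding=cfg.delay_coding)
    results = {}
    for nid, trains, reg in inputs:
        model = NeuronEncodingModel(
            trains, reg, neuron_id=nid, width=cfg.window_width_s,
            step=cfg.window_step_s, alpha=cfg.alpha,
            bonferroni_n=cfg.bonferroni_n)
        results[nid] = model.fit(include_eye=cfg.include_eye)
    n_task = sum(r.task_related for r in results.values())
    return {"n_neurons": len(results), "n_task_related": n_task,
            "_results": results, "_inputs": inputs}


def _vector_stage(enc: dict, ds: Dataset, cfg: PipelineConfig) -> dict:
    phase_bounds = {1: cfg.phase1_bounds_s, 2: cfg.phase2_bounds_s}
    rows = []
    raw_by_phase = {1: {}, 2: {}}
    std_by_phase = {1: {}, 2: {}}
    for nid, res in enc["_results"].items():
        if not res.task_related:
            continue
        vs = vector_series(res.betas)
        iR = res.betas.names.index("reward")
        iD = res.betas.names.index("delay")
        mean2 = res.betas.control_mean[[iR, iD]]
        sd2 = res.betas.control_sd[[iR, iD]]
        for ph in (1, 2):
            v = phase_sum(vs, phase_bounds[ph], phase=ph)
            raw_by_phase[ph][nid] = v
            # the per-neuron label uses raw betas; the population vector the
            # standardized ones (origin already removed in vector_series)
            std_by_phase[ph][nid] = standardize_vector(
                v, np.zeros(2), sd2)
            rows.append({"neuron_id": nid, "phase": ph,
                         "theta_deg": v.theta, "magnitude": v.magnitude,
                         "category": v.category,
                         "n_significant_bins": v.n_significant_bins})
    vec_table = pd.DataFrame(rows)
    stats_by_phase = {}
    for ph in (1, 2):
        vecs = list(std_by_phase[ph].values())
        try:
            stats_by_phase[ph] = population_stats(vecs)
        except ValueError as exc:
            logger.warning("population_stats phase %d skipped: %s", ph, exc)
            stats_by_phase[ph] = None
    fractions = {}
    for ph in (1, 2):
        sub = vec_table[(vec_table["phase"] == ph)
                        & (vec_table["category"] != "unclassified")]
        fractions[ph] = (sub["category"].value_counts(normalize=True)
                         .to_dict() if len(sub) else {})
    # anatomical / waveform contrasts for the signature categories
    contrasts = {}
    feats = ds.truth.set_index("neuron_id")[
        ["x_mm", "y_mm", "z_mm", "baseline_hz", "spike_width_ms",
         "spike_amp_uv"]]
    for ph, target in ((1, "Discounting-"), (2, "Compounding+")):
        sub = vec_table[vec_table["phase"] == ph]
        labels = sub.set_index("neuron_id")["category"]
        all_ids = ds.truth["neuron_id"]
        lab_full = np.array([labels.get(n, "unclassified") for n in all_ids])
        try:
            contrasts[f"phase{ph}_{target}"] = position_contrast(
                lab_full, feats.loc[all_ids], target)
        except ValueError as exc:
            logger.warning("position_contrast %s skipped: %s", target, exc)
    return {"table": vec_table, "population": stats_by_phase,
            "fractions": fractions, "contrasts": contrasts,
            "_raw": raw_by_phase}


def _pca_stage(enc: dict, cfg: PipelineConfig, seed: int,
               with_envelope: bool = True) -> dict:
    inputs = enc["_inputs"]
    trains = [t for _, t, _ in inputs]
    regs = [r for _, _, r in inputs]
    ids = [n for n, _, _ in inputs]
    grid = pca_grid()
    model = PopulationPCA.from_neurons(trains, regs, neuron_ids=ids, grid=grid)
    res = model.fit()
    out = {"explained_variance_pct": res.explained_variance_pct[:10].tolist(),
           "significant_pcs": [], "_result": res, "_envelope": None,
           "_masks": np.zeros((4, grid.n_bins), dtype=bool)}
    if with_envelope:
        env = surrogate_envelope(trains, regs, n_shuffles=cfg.n_shuffles,
                                 seed=seed, grid=grid, n_pcs=10)
        sig, masks = significant_pcs(res, env)
        out.update({"significant_pcs": sig, "_envelope": env,
                    "_masks": masks})
    return out


def _anatomy_stage(pca: dict, ds: Dataset, cfg: PipelineConfig, seed: int) -> dict:
    res = pca["_result"]
    pos = (ds.truth.set_index("neuron_id")
           .loc[res.neuron_ids, ["x_mm", "y_mm", "z_mm"]].to_numpy())
    out = {}
    for pc in (0, 1):
        scan = gradient_scan(res.scores[:, pc], pos, n_perm=200, seed=seed + pc)
        out[f"pc{pc + 1}"] = {
            "best_direction": scan.best_direction.tolist(),
            "rho": scan.best_rho, "p_raw": scan.best_p,
            "p_family": scan.p_family,
        }
        out[f"_scan_pc{pc + 1}"] = scan
    return out


def run_pipeline(config: PipelineConfig, out_dir=None) -> dict:
    """Execute all stages in dependency order and return the run report.

    With ``out_dir`` set, every intermediate artifact (trials.csv,
    spikes.csv, neurons.csv, eye.h5, truth.json, rejection_rates.csv,
    behavior_fit.json, betas.csv, vectors.csv, pca_variance.csv,
    eigenvectors.csv, scores.csv, anatomy.csv, report.json) is written.
    """
    t0 = time.time()
    cfg = config
    cfg.sim.seed = cfg.seed
    report = {"software_version": __version__, "config": cfg.to_dict(),
              "config_hash": cfg.config_hash()}
    stage = "simulate"
    try:
        ds = generate_dataset(cfg.sim)
        report["simulate"] = {
            "n_trials": int(len(ds.trials)),
            "n_rejected": int((ds.trials["outcome"] == "rejected").sum()),
            "n_neurons": int(len(ds.truth)),
        }
        stage = "behavior"
        beh = _behavior_stage(ds, cfg)
        report["behavior"] = {k: v for k, v in beh.items()
                              if not k.startswith("_")}
        stage = "encoding"
        enc = _encoding_stage(ds, cfg)
        report["encoding"] = {k: v for k, v in enc.items()
                              if not k.startswith("_")}
        stage = "vectors"
        vec = _vector_stage(enc, ds, cfg)
        report["vectors"] = {
            "category_fractions": vec["fractions"],
            "population": {
                str(ph): (None if s is None else
                          {k: v for k, v in s.items()})
                for ph, s in vec["population"].items()},
            "contrasts": vec["contrasts"],
        }
        stage = "pca"
        pca = _pca_stage(enc, cfg, cfg.seed + 1)
        report["pca"] = {k: v for k, v in pca.items() if not k.startswith("_")}
        stage = "anatomy"
        anat = _anatomy_stage(pca, ds, cfg, cfg.seed + 2)
        report["anatomy"] = {k: v for k, v in anat.items()
                             if not k.startswith("_")}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    report["wall_time_s"] = round(time.time() - t0, 3)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        stnio.write_dataset(ds, out)
        beh["_table"].to_csv(out / "rejection_rates.csv", index=False)
        (out / "behavior_fit.json").write_text(json.dumps(
            report["behavior"], indent=1, default=float))
        _write_betas(enc["_results"], out / "betas.csv")
        _write_anova(enc["_results"], out / "anova.csv")
        vec["table"].to_csv(out / "vectors.csv", index=False)
        _write_pca(pca, out)
        anat["_scan_pc1"].table.to_csv(out / "anatomy.csv", index=False)
        (out / "report.json").write_text(
            json.dumps(report, indent=1, default=_json_default))
    return report


def _write_pca(pca: dict, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    res = pca["_result"]
    pd.DataFrame({
        "pc": np.arange(1, 11),
        "variance_pct": res.explained_variance_pct[:10],
        "significant": [i in pca["significant_pcs"] for i in range(10)],
    }).to_csv(out / "pca_variance.csv", index=False)
    frames = []
    for pc in range(4):
        f = res.eigenvector_series(pc)
        f.insert(0, "pc", pc + 1)
        f["significant"] = pca["_masks"][pc]
        frames.append(f)
    pd.concat(frames).to_csv(out / "eigenvectors.csv", index=False)
    score_df = pd.DataFrame(res.scores[:, :4],
                            columns=[f"pc{i}" for i in range(1, 5)])
    score_df.insert(0, "neuron_id", res.neuron_ids)
    score_df.to_csv(out / "scores.csv", index=False)
    env = pca["_envelope"]
    if env is not None:
        (out / "envelope.json").write_text(json.dumps({
            "n_shuffles": env.n_shuffles, "seed": env.seed,
            "variance_lo": env.variance_lo.tolist(),
            "variance_hi": env.variance_hi.tolist(),
        }, indent=1))


def _write_anova(results: dict, path) -> None:
    rows = []
    for nid, res in results.items():
        a = res.anova
        for j, c in enumerate(a.centers):
            rows.append((nid, c, a.F["reward"][j], a.p["reward"][j],
                         bool(a.flags["reward"][j]),
                         a.F["delay"][j], a.p["delay"][j],
                         bool(a.flags["delay"][j]),
                         a.F["interaction"][j], a.p["interaction"][j],
                         bool(a.flags["interaction"][j])))
    pd.DataFrame(rows, columns=[
        "neuron_id", "bin_center_s", "F_reward", "p_reward", "sig_reward",
        "F_delay", "p_delay", "sig_delay", "F_interaction", "p_interaction",
        "sig_interaction"]).to_csv(path, index=False)


def _write_betas(results: dict, path) -> None:
    rows = []
    for nid, res in results.items():
        b = res.betas
        iR, iD = b.names.index("reward"), b.names.index("delay")
        for j, c in enumerate(b.centers):
            rows.append((nid, c, b.betas[j, iR], b.betas[j, iD],
                         b.p[j, iR], b.p[j, iD],
                         bool(b.sig[j, iR]), bool(b.sig[j, iD])))
    pd.DataFrame(rows, columns=[
        "neuron_id", "bin_center_s", "beta_R", "beta_D", "p_R", "p_D",
        "sig_R", "sig_D"]).to_csv(path, index=False)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
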