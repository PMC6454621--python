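"""Pipeline orchestration: synthesize -> preprocess -> characterize ->
decode (and/or simulate), with a provenance manifest per run."""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np

from . import __version__
from .protocols import make_protocol, ISOTONIC
from .session import read_session, write_session
from .synthesis import (default_templates, generate_ground_truth_trains,
                        synthesize_session)
from .preprocess import (sort_session, select_trials, estimate_firing_rate,
                         envelope, compute_snr)
from .characterize import fit_fr_force, compute_fr_slope, fit_slope_velocity
from .decode import (make_trials, leave_one_out, balanced_accuracy,
                     chance_level)


class StageError(RuntimeError):
    def __init__(self, stage, exc):
        super().__init__(f"stage {stage!r} failed: {exc}")
        self.stage = stage


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()


def write_manifest(out_dir: Path, config: dict, seed: int,
                   stages: list[str], timings: dict) -> Path:
    manifest = {
        "package": "mngpipe", "version": __version__,
        "config_hash": _config_hash(config), "config": config,
        "seed": seed, "stages": stages, "timings_s": timings,
    }
    p = Path(out_dir) / "manifest.json"
    p.write_text(json.dumps(manifest, indent=1, default=str))
    return p


def synthesize_stage(params: dict, seed: int, out_dir: Path) -> Path:
    task = params.get("task", ISOTONIC)
    levels = params.get("levels", [1, 2, 4, 6] if task == ISOTONIC
                        else [17, 26, 47])
    proto = make_protocol(task, levels, params.get("reps_per_level", 3))
    n_units = params.get("n_units", 10)
    rate_law = params.get(
        "rate_law", "saturating_isotonic" if task == ISOTONIC else "ramp_isokinetic")
    trains = generate_ground_truth_trains(proto, n_units, rate_law, seed)
    templates = default_templates(n_units, cycle=True)
    sess = synthesize_session(
        proto, trains, templates,
        noise_sd=params.get("noise_sd", 0.08),
        semg_corr_target=params.get("semg_corr_target", 0.6),
        seed=seed)
    return write_session(sess, Path(out_dir) / "session",
                         store=params.get("store", "hdf5"))


def preprocess_stage(params: dict, out_dir: Path) -> dict:
    sess = read_session(Path(out_dir) / "session")
    units, filtered = sort_session(
        sess, detection_k=params.get("detection_k", 4.0),
        max_units=params.get("max_units", 5))
    selection = select_trials(sess, filtered_mng=filtered)
    pdir = Path(out_dir) / "preprocess"
    pdir.mkdir(parents=True, exist_ok=True)
    for u in units:
        np.savetxt(pdir / f"unit{u.unit_id}_spikes.csv", u.spike_times,
                   fmt="%.6f", header="spike_time_s")
    snr = compute_snr(filtered, sess.protocol.cue_times,
                      sess.protocol.rest_intervals(), fs=sess.fs)
    report = {"n_units": len(units), "selection": selection.to_dict(),
              "session_snr": snr.to_dict()}
    (pdir / "report.json").write_text(json.dumps(report, indent=1))
    return report


def characterize_stage(params: dict, out_dir: Path) -> dict:
    sess = read_session(Path(out_dir) / "session")
    units, filtered = sort_session(sess)
    proto = sess.protocol
    t = np.arange(0.0, proto.total_duration, 0.001)
    frs = [estimate_firing_rate(u.spike_times, t) for u in units]
    afr = np.mean(frs, axis=0) if frs else np.zeros_like(t)
    report: dict = {}
    if proto.task == ISOTONIC:
        peaks, plats, forces = [], [], []
        t_p = np.arange(len(sess.pressure)) / sess.pressure_fs
        for (start, stop), level in zip(proto.cue_times, proto.rep_levels):
            m = (t >= start) & (t < stop)
            hold = (t >= start + 2.5) & (t < stop)
            mp = (t_p >= start + 1.5) & (t_p < stop)
            if m.any() and mp.any():
                peaks.append(afr[m].max())
                plats.append(afr[hold].mean())
                forces.append(sess.pressure[mp].mean())
        x = np.asarray(forces) / max(forces)
        report["fr_force_fit_reaching"] = fit_fr_force(
            x, np.asarray(peaks) / max(peaks), phase="reaching").to_dict()
        report["fr_force_fit_holding"] = fit_fr_force(
            x, np.asarray(plats) / max(plats), phase="holding").to_dict()
    else:
        slopes, vels = [], []
        for (start, stop), level in zip(proto.cue_times, proto.rep_levels):
            m = (t >= start - proto.rest_duration) & (t < stop)
            slopes.append(compute_fr_slope(afr[m], t[m], start))
            vels.append(level)
        fit = fit_slope_velocity(vels, slopes)
        report["slope_velocity_fit"] = fit.to_dict()
    cdir = Path(out_dir) / "characterize"
    cdir.mkdir(parents=True, exist_ok=True)
    (cdir / "report.json").write_text(json.dumps(report, indent=1))
    return report


def decode_stage(params: dict, out_dir: Path) -> dict:
    sess = read_session(Path(out_dir) / "session")
    units, filtered = sort_session(sess)
    if not units:
        raise RuntimeError("no sorted units; cannot decode")
    task = "force" if sess.protocol.task == ISOTONIC else "velocity"
    env = envelope(filtered, fs=sess.fs)
    trials = make_trials(sess, units, mng_env=env)
    variant = params.get("variant", "custom")
    cm, _models = leave_one_out(trials, task, variant=variant)
    acc = balanced_accuracy(cm.counts)
    n_levels = len(sess.protocol.levels)
    report = {
        "task": task, "variant": variant, "balanced_accuracy": acc,
        "chance_with_rest": chance_level(n_levels, include_rest=True),
        "chance_without_rest": chance_level(n_levels, include_rest=False),
        "classes": cm.classes, "confusion": cm.counts.tolist(),
    }
    ddir = Path(out_dir) / "decode"
    ddir.mkdir(parents=True, exist_ok=True)
    (ddir / "report.json").write_text(json.dumps(report, indent=1))
    return report


STAGES = {
    "synthesize": lambda p, seed, out: synthesize_stage(p, seed, out),
    "preprocess": lambda p, seed, out: preprocess_stage(p, out),
    "characterize": lambda p, seed, out: characterize_stage(p, out),
    "decode": lambda p, seed, out: decode_stage(p, out),
}


def run_pipeline(config: dict) -> dict:
    """Execute the configured stages in order; write outputs and a
    provenance manifest into ``config['out_dir']``."""
    stages = config.get("stages", ["synthesize"])
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stages {unknown}")
    seed = int(config.get("seed", 0))
    out_dir = Path(config.get("out_dir", "mngpipe_run"))
    out_dir.mkdir(parents=True, exist_ok=True)
    timings, reports = {}, {}
    for stage in stages:
        t0 = time.perf_counter()
        try:
            reports[stage] = STAGES[stage](config.get(stage, {}), seed,
                                           out_dir)
        except Exception as exc:
            raise StageError(stage, exc) from exc
        timings[stage] = round(time.perf_counter() - t0, 3)
    write_manifest(out_dir, config, seed, stages, timings)
    return {"out_dir": str(out_dir), "stages": stages, "timings": timings,
            "reports": {k: str(v) if isinstance(v, Path) else v
                        for k, v in reports.items()}}
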