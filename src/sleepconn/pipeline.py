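"""End-to-end orchestration: simulate -> code-sleep -> build-connectomes ->
compare-states, with a JSON manifest tying every output to its inputs.

Stages communicate through files in a study directory so each can be run
(or re-run) independently from the CLI; `run_pipeline` chains them and is
fully deterministic given the config seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import connectome as conn
from . import resp, sleepcode, stats, synth
from .config import StudyConfig, config_hash, save_config
from .errors import InsufficientSignalError

logger = logging.getLogger("sleepconn")

__all__ = ["simulate_study", "code_sleep_stage", "connectome_stage",
           "compare_stage", "run_pipeline", "load_manifest",
           "session_concordance"]


def _infant_dir(out: Path, infant_id: str) -> Path:
    d = out / infant_id
    d.mkdir(parents=True, exist_ok=True)
    return d


def simulate_study(cfg: StudyConfig, out: str | Path) -> dict:
    """Generate and write every infant session; returns the manifest."""
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    save_config(cfg, out / "config.yaml")
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(cfg.n_infants + 1)
    rng_meta = np.random.default_rng(int(children[-1].generate_state(1)[0] % (2 ** 31)))
    effect = (synth.EffectMap(cfg.effect_edges, cfg.effect_delta_z)
              if cfg.effect_edges else None)
    resp_params = {synth.AS: cfg.resp_as, synth.QS: cfg.resp_qs}
    manifest: dict = {"seed": cfg.seed, "config_hash": config_hash(cfg), "infants": []}
    for i in range(cfg.n_infants):
        infant_id = f"sub-{i + 1:02d}"
        seed_i = int(children[i].generate_state(1)[0] % (2 ** 31))
        n_runs = int(rng_meta.integers(cfg.runs_min, cfg.runs_max + 1))
        pma = float(np.clip(45.9 + 1.2 * rng_meta.standard_normal(), 42.0, 47.0))
        sex = int(rng_meta.integers(2))
        session = synth.generate_session(
            session_s=cfg.session_s, n_runs=n_runs, n_nodes=cfg.n_nodes,
            n_volumes=cfg.n_volumes, tr=cfg.tr, bout_params=cfg.bout,
            resp_params=resp_params, effect=effect,
            motion_outlier_prob=cfg.motion_outlier_prob,
            infant_id=infant_id, pma_weeks=pma, sex=sex, seed=seed_i)
        d = _infant_dir(out, infant_id)
        resp.write_physio(session.respiration, d / infant_id)
        runs_df = pd.DataFrame(
            [{"run_id": r.run_id, "onset_s": r.onset,
              "n_volumes": r.n_volumes, "tr_s": r.tr} for r in session.runs])
        runs_df.to_csv(d / "runs.tsv", sep="\t", index=False)
        for r in session.runs:
            np.savetxt(d / f"motion_{r.run_id}.tsv", session.motion[r.run_id],
                       delimiter="\t", header="trans_x\ttrans_y\ttrans_z\trot_x\trot_y\trot_z",
                       comments="")
            np.savetxt(d / f"tissue_{r.run_id}.tsv", session.tissue_means[r.run_id],
                       delimiter="\t", header="csf\twm\tgm", comments="")
            ts = session.node_series[r.run_id]
            np.savetxt(d / f"nodes_{r.run_id}.tsv", ts.data, delimiter="\t",
                       header="\t".join(ts.node_ids), comments="")
        truth = {
            "timeline": [list(e) for e in session.timeline.entries],
            "session_duration": session.timeline.session_duration,
            "true_run_states": list(session.true_run_states),
            "effect_edges": list(cfg.effect_edges),
            "effect_delta_z": cfg.effect_delta_z,
        }
        (d / "truth.json").write_text(json.dumps(truth, indent=1))
        manifest["infants"].append({
            "id": infant_id, "seed": seed_i, "pma_weeks": pma, "sex": sex,
            "n_runs": n_runs, "dir": str(d.relative_to(out)),
        })
        logger.info("simulated %s: %d runs, seed %d", infant_id, n_runs, seed_i)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def load_manifest(out: str | Path) -> dict:
    return json.loads((Path(out) / "manifest.json").read_text())


def code_sleep_stage(cfg: StudyConfig, out: str | Path) -> dict:
    """Code sleep per infant: hypnogram TSV + run assignment TSV.

    Returns the updated manifest with per-run assignments and the
    epoch-level concordance against synthetic ground truth.
    """
    out = Path(out)
    manifest = load_manifest(out)
    for infant in manifest["infants"]:
        d = out / infant["dir"]
        infant_id = infant["id"]
        trace = resp.read_physio(d / f"{infant_id}_physio.tsv.gz")
        filtered = resp.bandpass(trace, cfg.bandpass_low_hz, cfg.bandpass_high_hz)
        try:
            breaths = resp.detect_breaths(filtered)
        except InsufficientSignalError:
            breaths = None
            logger.warning("%s: breath detection failed; all epochs IND", infant_id)
        windows = sleepcode.epoch_windows(0.0, trace.duration, cfg.epoch_s)
        feats = sleepcode.extract_features(filtered, breaths, windows, cfg.thresholds)
        labels = [sleepcode.classify_epoch(f, cfg.thresholds) for f in feats]
        bouts = sleepcode.segment_states(labels, cfg.epoch_s)
        runs_df = pd.read_csv(d / "runs.tsv", sep="\t")
        runs = [synth.RunBoundary(r.run_id, r.onset_s, int(r.n_volumes), r.tr_s)
                for r in runs_df.itertuples()]
        mean_fd = {}
        for r in runs:
            motion = np.loadtxt(d / f"motion_{r.run_id}.tsv", skiprows=1)
            _, mean_fd[r.run_id] = conn.compute_fd(motion, cfg.head_radius_mm)
        assignments = sleepcode.assign_run_state(bouts, runs, mean_fd,
                                                 cfg.fd_threshold_mm)
        pd.DataFrame([{"label": b.label, "start_s": b.start, "end_s": b.end}
                      for b in bouts]).to_csv(d / "hypnogram.tsv", sep="\t", index=False)
        pd.DataFrame([a.__dict__ for a in assignments]).to_csv(
            d / "assignments.tsv", sep="\t", index=False)
        for a in assignments:
            if not a.included:
                logger.warning("%s/%s excluded (%s)", infant_id, a.run_id,
                               a.exclusion_reason)
        truth = json.loads((d / "truth.json").read_text())
        timeline = synth.StateTimeline(
            tuple(tuple(e) for e in truth["timeline"]), truth["session_duration"])
        infant["assignments"] = [a.__dict__ for a in assignments]
        infant["concordance"] = sleepcode.concordance(
            labels, timeline.epoch_truth(windows))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def connectome_stage(cfg: StudyConfig, out: str | Path) -> dict:
    """Build Fisher-z connectomes for every included run.

    Motion-excluded and indeterminate runs never reach connectome
    construction.
    """
    out = Path(out)
    manifest = load_manifest(out)
    for infant in manifest["infants"]:
        d = out / infant["dir"]
        for a in infant.get("assignments", []):
            if not a["included"]:
                continue
            run_id = a["run_id"]
            data = np.loadtxt(d / f"nodes_{run_id}.tsv", skiprows=1)
            motion = np.loadtxt(d / f"motion_{run_id}.tsv", skiprows=1)
            tissue = np.loadtxt(d / f"tissue_{run_id}.tsv", skiprows=1)
            ts = conn.NodeTimeSeries(run_id, data, cfg.tr)
            cmat = conn.preprocess_run(ts, motion, tissue, cfg.smooth_cutoff_hz)
            np.savetxt(d / f"connectome_{run_id}.csv", cmat.matrix, delimiter=",")
            i, j = conn.edge_pairs(cmat.n_nodes)
            pd.DataFrame({"i": i, "j": j, "z": cmat.edge_vector()}).to_csv(
                d / f"edges_{run_id}.tsv", sep="\t", index=False)
            a["connectome"] = f"{infant['dir']}/connectome_{run_id}.csv"
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def compare_stage(cfg: StudyConfig, out: str | Path) -> dict:
    """Edgewise AS-vs-QS mixed-effects comparison across included runs."""
    out = Path(out)
    manifest = load_manifest(out)
    rows, z_rows = [], []
    for infant in manifest["infants"]:
        d = out / infant["dir"]
        for a in infant.get("assignments", []):
            if not a["included"]:
                continue
            edges = pd.read_csv(d / f"edges_{a['run_id']}.tsv", sep="\t")
            z_rows.append(edges["z"].to_numpy())
            rows.append({"participant": infant["id"],
                         "state": 1 if a["label"] == synth.AS else 0,
                         "pma_weeks": infant["pma_weeks"], "sex": infant["sex"],
                         "mean_fd": a["mean_fd"]})
    design = pd.DataFrame(rows)
    result: dict = {"n_runs_analysed": len(rows)}
    if rows and design["state"].nunique() == 2 and design["participant"].nunique() >= 2:
        Z = np.vstack(z_rows)
        edge_idx = conn.edge_pairs(cfg.n_nodes)
        es = stats.edgewise_analysis(Z, design, cfg.adjust, edge_index=edge_idx)
        es.table.to_csv(out / "edge_stats.csv", index=False, float_format="%.8g")
        summary = stats.effect_size_summary(es.table["cohens_d"].to_numpy())
        result.update(summary.to_dict())
        result["n_significant_by"] = int((es.table["q_by"] < cfg.alpha).sum())
        counts, bin_edges = np.histogram(es.table["cohens_d"], bins=40,
                                         range=(-2.0, 2.0))
        pd.DataFrame({"bin_left": bin_edges[:-1], "bin_right": bin_edges[1:],
                      "count": counts}).to_csv(out / "effect_hist.tsv",
                                               sep="\t", index=False)
    else:
        logger.warning("comparison skipped: need runs from both states and >=2 infants")
        result["skipped"] = "need runs from both states and >=2 participants"
    (out / "stats_summary.json").write_text(json.dumps(result, indent=1))
    manifest["stats"] = result
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def session_concordance(seed: int, session_s: float = 3600.0,
                        cfg: StudyConfig | None = None) -> float:
    """Epoch-level coder-vs-ground-truth concordance for one synthetic session.

    Generates a timeline and respiration in memory, codes 30-s epochs with
    the configured thresholds, and returns the fraction of non-IND epochs
    whose label matches the generating state (majority occupancy per
    epoch).  NaN when every epoch is indeterminate.
    """
    cfg = cfg or StudyConfig()
    ss = np.random.SeedSequence(seed)
    s_tl, s_resp = (int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(2))
    timeline = synth.generate_timeline(session_s, cfg.bout, seed=s_tl)
    trace = synth.generate_respiration(
        timeline, {synth.AS: cfg.resp_as, synth.QS: cfg.resp_qs}, seed=s_resp)
    filtered = resp.bandpass(trace, cfg.bandpass_low_hz, cfg.bandpass_high_hz)
    try:
        breaths = resp.detect_breaths(filtered)
    except InsufficientSignalError:
        breaths = None
    windows = sleepcode.epoch_windows(0.0, trace.duration, cfg.epoch_s)
    feats = sleepcode.extract_features(filtered, breaths, windows, cfg.thresholds)
    labels = [sleepcode.classify_epoch(f, cfg.thresholds) for f in feats]
    return sleepcode.concordance(labels, timeline.epoch_truth(windows))


def run_pipeline(cfg: StudyConfig, out: str | Path) -> dict:
    """Run all stages in order; halts after a failed stage with a partial
    manifest on disk."""
    simulate_study(cfg, out)
    code_sleep_stage(cfg, out)
    connectome_stage(cfg, out)
    return compare_stage(cfg, out)
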