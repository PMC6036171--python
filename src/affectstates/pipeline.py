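"""End-to-end orchestration: simulate, estimate, decode, select, test.

A single configuration dict (YAML-friendly) drives every stage; per-stage
seeds derive from one master seed so a run is reproducible bit-for-bit.
The result is a :class:`RunManifest` (config hash, seeds, QC counters) and
a report aggregating accuracy tables over the full/reliable/unreliable
stimulus sets plus the downstream statistics.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import synthetic
from .catalog import select_max_separation
from .design import build_design
from .dip import bootstrap_multimodality_p
from .effects import glmm_effect_size
from .encoding import group_maps, subject_encoding
from .gs import gs_fit_project
from .lss import BetaSeries, fit_bold_lss
from .mvpa import (accuracy_summary, affective_state_accuracy, loocv_classify,
                   loocv_regress_scr)
from .scr import fit_scr_betas, preprocess_scr
from .subsets import build_subsets, simulate_chance_subset_size

__all__ = ["RunManifest", "run_pipeline", "default_config", "stage_seed"]

STAGES = ("pool", "design", "betas", "bold", "scr", "mvpa", "subsets",
          "dipscan", "effects", "encoding")


def default_config() -> dict:
    """Desk-scale defaults: 19 subjects, 90+30 stimuli, 2000 voxels, 2 runs."""
    return {
        "seed": 0,
        "n_subjects": 19,
        "n_stimuli_pool": 1000,
        "n_extrinsic": 90,
        "n_intrinsic": 30,
        "n_voxels": 2000,
        "n_runs": 2,
        "coupling": 0.5,
        "noise_sd": 1.0,
        "spatial_corr": 0.0,
        "incongruent_fraction": 0.0,
        "amplitude_mode": "continuous",
        "signal_gain": 0.25,
        "signed_amplitude": 1.0,
        "scr_amp_slope": 0.3,
        "sampling_rate": 100.0,
        "n_reps": 30,
        "bold_forward": False,   # True: simulate BOLD runs and invert via LSS
        "bold_noise_sd": 1.0,
        "run_scr": True,
        "scr_corrupt_runs": [],  # [subject_index, run] pairs forced flat
        "n_boot": 1000,
        "n_chance_sims": 1000,
        "group_encoding": True,
        "alpha": 0.05,
    }


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclass
class RunManifest:
    """Traceability record of one pipeline run."""

    config_hash: str
    seeds: dict
    qc: dict = field(default_factory=dict)
    stages_run: list = field(default_factory=list)


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _summarize(summary: dict) -> dict:
    return {"mean": summary["mean"], "ci95": list(summary["ci95"]),
            "n_subjects": summary["n_subjects"]}


def run_pipeline(config: dict | None = None) -> tuple[RunManifest, dict]:
    cfg = default_config()
    if config:
        cfg.update(config)
    master = int(cfg["seed"])
    canon = json.dumps(cfg, sort_keys=True, default=str)
    manifest = RunManifest(
        config_hash=hashlib.sha256(canon.encode()).hexdigest()[:16],
        seeds={s: stage_seed(master, s) for s in STAGES})
    report: dict = {"config": cfg}

    stage = "pool"
    try:
        pool = synthetic.gen_stimulus_pool(cfg["n_stimuli_pool"],
                                          cfg["coupling"],
                                          manifest.seeds["pool"])
        n_total = cfg["n_extrinsic"] + cfg["n_intrinsic"]
        chosen = select_max_separation(pool, n_total)
        ext_ids = chosen[:cfg["n_extrinsic"]]
        int_ids = chosen[cfg["n_extrinsic"]:]
        catalog = pool[pool["stimulus_id"].isin(chosen)].reset_index(drop=True)
        manifest.stages_run.append(stage)

        stage = "design"
        design = build_design(catalog, ext_ids, int_ids,
                              n_runs=cfg["n_runs"],
                              seed=manifest.seeds["design"])
        manifest.stages_run.append(stage)
        report["design"] = design.report

        stage = "betas"
        scfg = synthetic.SyntheticConfig(
            n_subjects=cfg["n_subjects"], n_extrinsic=cfg["n_extrinsic"],
            n_intrinsic=cfg["n_intrinsic"], n_voxels=cfg["n_voxels"],
            n_runs=cfg["n_runs"], coupling=cfg["coupling"],
            noise_sd=cfg["noise_sd"], spatial_corr=cfg["spatial_corr"],
            incongruent_fraction=cfg["incongruent_fraction"],
            amplitude_mode=cfg["amplitude_mode"],
            signal_gain=cfg["signal_gain"],
            signed_amplitude=cfg["signed_amplitude"],
            scr_amp_slope=cfg["scr_amp_slope"],
            sampling_rate=cfg["sampling_rate"], seed=master)
        rng = np.random.default_rng(manifest.seeds["betas"])
        patterns = synthetic.gen_encoding_patterns(cfg["n_voxels"], rng)
        incongruent = synthetic.pick_incongruent(
            np.asarray(ext_ids), cfg["incongruent_fraction"], rng)
        gm, truths = {}, {}
        for s in range(cfg["n_subjects"]):
            noisy, truth = synthetic.gen_subject_betas(
                catalog, design, scfg, patterns, incongruent,
                seed=np.random.SeedSequence([manifest.seeds["betas"], s]))
            truths[s] = truth
            if cfg["bold_forward"]:
                runs = synthetic.gen_bold(
                    design, noisy, noise_sd=cfg["bold_noise_sd"],
                    seed=np.random.SeedSequence([manifest.seeds["bold"], s]))
                gm[s] = fit_bold_lss(runs, design, subject=s)
            else:
                is_ext = truth.extrinsic_rows(design)
                gm[s] = BetaSeries(data=noisy[is_ext], modality="GM",
                                   stimulus_ids=design.events.loc[
                                       is_ext, "stimulus_id"].to_numpy(),
                                   subject=s)
        manifest.stages_run.append(stage)

        stage = "scr"
        scr_betas = {}
        excluded_runs = 0
        total_runs = cfg["n_subjects"] * cfg["n_runs"]
        corrupt = {tuple(p) for p in cfg["scr_corrupt_runs"]}
        if cfg["run_scr"]:
            for s in range(cfg["n_subjects"]):
                traces = synthetic.gen_scr(
                    design, truths[s].scr_amplitudes, scfg,
                    seed=np.random.SeedSequence([manifest.seeds["scr"], s]))
                processed = []
                for r, tr in enumerate(traces):
                    if (s, r) in corrupt:
                        tr = np.zeros_like(tr)
                    processed.append(preprocess_scr(tr, cfg["sampling_rate"]))
                excluded_runs += sum(p.degenerate for p in processed)
                scr_betas[s] = fit_scr_betas(processed, design,
                                             fs_design=cfg["sampling_rate"],
                                             subject=s)
        manifest.qc["runs_total"] = total_runs
        manifest.qc["runs_excluded"] = excluded_runs
        manifest.qc["excluded_data_fraction"] = (
            excluded_runs / total_runs if total_runs else 0.0)
        manifest.stages_run.append(stage)

        stage = "mvpa"
        lab = catalog.set_index("stimulus_id")
        gs_coords = {}
        preds = {"valence": [], "arousal": []}
        scr_preds = []
        for s in range(cfg["n_subjects"]):
            _, coords = gs_fit_project(gm[s])
            gs_coords[s] = coords
            for prop, col in (("valence", "val_label"), ("arousal", "aro_label")):
                labels = lab.loc[coords.stimulus_ids, col].to_numpy(int)
                preds[prop].append(loocv_classify(
                    coords, labels, prop, n_reps=cfg["n_reps"],
                    seed=manifest.seeds["mvpa"]))
            if cfg["run_scr"] and s in scr_betas:
                scr_preds.append(loocv_regress_scr(coords, scr_betas[s]))
        val_preds = pd.concat(preds["valence"], ignore_index=True)
        aro_preds = pd.concat(preds["arousal"], ignore_index=True)
        report["fss"] = {
            "valence": _summarize(accuracy_summary(val_preds)),
            "arousal": _summarize(accuracy_summary(aro_preds)),
            "AS": _summarize(accuracy_summary(
                affective_state_accuracy(val_preds, aro_preds))),
        }
        manifest.stages_run.append(stage)

        stage = "subsets"
        parts = {"valence": build_subsets(val_preds, cfg["alpha"]),
                 "arousal": build_subsets(aro_preds, cfg["alpha"])}
        for name, table in (("rss", lambda p: p.rss), ("uss", lambda p: p.uss)):
            report[name] = {}
            for prop, pred in (("valence", val_preds), ("arousal", aro_preds)):
                sets = table(parts[prop])
                if all(len(v) for v in sets.values()):
                    report[name][prop] = _summarize(
                        accuracy_summary(pred, subset=sets))
                else:
                    report[name][prop] = None  # empty set for some subject
        report["subset_sizes"] = {
            prop: {"joint_rss": len(parts[prop].joint_rss),
                   "joint_uss": len(parts[prop].joint_uss)}
            for prop in parts}
        report["chance_simulation"] = {}
        for prop, pred in (("valence", val_preds), ("arousal", aro_preds)):
            macc = report["fss"][prop]["mean"]
            sizes = [len(parts[prop].rss[s]) for s in parts[prop].rss]
            usizes = [len(parts[prop].uss[s]) for s in parts[prop].uss]
            sim = simulate_chance_subset_size(
                macc, n_subjects=cfg["n_subjects"],
                n_stimuli=cfg["n_extrinsic"], n_sims=cfg["n_chance_sims"],
                seed=stage_seed(master, f"chance-{prop}"),
                observed_rss=int(np.mean(sizes)),
                observed_uss=int(np.mean(usizes)))
            report["chance_simulation"][prop] = {
                "p_rss": sim["p_rss"], "p_uss": sim["p_uss"],
                "expected_rss_fraction": sim["expected_rss_fraction"],
                "expected_uss_fraction": sim["expected_uss_fraction"]}
        manifest.stages_run.append(stage)

        stage = "dipscan"
        report["dip"] = {}
        coords_full = catalog.set_index("stimulus_id").loc[
            ext_ids, ["val_mean", "aro_mean"]].to_numpy(float)
        id_pos = {sid: k for k, sid in enumerate(ext_ids)}
        for prop in ("valence", "arousal"):
            joint = sorted(parts[prop].joint_rss)
            if len(joint) >= 4:
                sub = coords_full[[id_pos[s] for s in joint]]
                scan = bootstrap_multimodality_p(
                    sub, coords_full, prop, n_boot=cfg["n_boot"],
                    seed=stage_seed(master, f"dip-{prop}"))
                report["dip"][prop] = {"theta_star": scan.theta_star,
                                       "dip_star": scan.dip_star,
                                       "p": scan.p}
            else:
                report["dip"][prop] = None
        manifest.stages_run.append(stage)

        stage = "effects"
        if cfg["run_scr"] and scr_preds:
            sp = pd.concat(scr_preds, ignore_index=True)
            eff = glmm_effect_size(sp["y_true"].to_numpy(),
                                   sp["y_pred"].to_numpy(),
                                   sp["subject"].to_numpy())
            report["scr_effect_fss"] = {"r": eff.r, "slope": eff.slope,
                                        "p": eff.p, "singular": eff.singular}
            rss_a = parts["arousal"].rss
            keep = np.array([sid in rss_a.get(subj, set()) for subj, sid in
                             zip(sp["subject"], sp["stimulus_id"])])
            if keep.sum() >= 3 * cfg["n_subjects"]:
                sub = sp[keep]
                try:
                    eff_r = glmm_effect_size(sub["y_true"].to_numpy(),
                                             sub["y_pred"].to_numpy(),
                                             sub["subject"].to_numpy())
                    report["scr_effect_rss"] = {"r": eff_r.r,
                                                "slope": eff_r.slope,
                                                "p": eff_r.p,
                                                "singular": eff_r.singular}
                except ValueError:
                    report["scr_effect_rss"] = None
            else:
                report["scr_effect_rss"] = None
        manifest.stages_run.append(stage)

        stage = "encoding"
        if cfg["group_encoding"]:
            report["encoding"] = {}
            for prop, col in (("valence", "val_label"), ("arousal", "aro_label")):
                encs = []
                for s in range(cfg["n_subjects"]):
                    labels = lab.loc[gm[s].stimulus_ids, col].to_numpy(int)
                    encs.append(subject_encoding(
                        gm[s], labels, n_reps=min(cfg["n_reps"], 10),
                        seed=manifest.seeds["encoding"]))
                gmap = group_maps(encs)
                planted = (truths[0].pattern_valence if prop == "valence"
                           else truths[0].pattern_arousal)
                r = float(np.corrcoef(gmap.mean, planted)[0, 1])
                report["encoding"][prop] = {
                    "n_significant": int(np.sum(np.isfinite(gmap.t)
                                                & (np.abs(gmap.t) > 2.10))),
                    "r_vs_planted": r}
        manifest.stages_run.append(stage)
    except Exception as exc:  # noqa: BLE001 - annotate and re-raise
        if isinstance(exc, StageFailure):
            raise
        raise StageFailure(stage, exc) from exc

    return manifest, report
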