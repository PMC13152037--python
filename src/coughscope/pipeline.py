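"""End-to-end experiment driver: simulate -> featurize -> k-fold train ->
evaluate -> noise robustness, with provenance and artifact hashing."""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import asdict

import numpy as np

from .config import RunConfig
from .evaluation import (aggregate_folds, confusion_matrix, metrics_from_confusion,
                         noise_robustness_eval, plot_confusion_matrix)
from .features import featurize_segments
from .nn.resnet import NetworkConfig
from .synth import DEFAULT_CLASS_SPECS, HARD_CLASS_SPECS, TABLE1_COUNTS, generate_segments
from .training import TrainConfig, cross_validate

log = logging.getLogger("coughscope")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed fan-out from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _hash_file(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_experiment(cfg: RunConfig) -> str:
    """Execute all stages; returns the run directory.

    Artifacts: per-fold history CSVs and checkpoints, aggregated metrics
    JSON, confusion-matrix CSV + PNG, noise table CSV, MANIFEST.json of
    artifact hashes, and the serialized config.
    """
    out = cfg.out_dir
    os.makedirs(out, exist_ok=True)
    t0 = time.time()
    stage = "simulate"
    try:
        with open(os.path.join(out, "config.yaml"), "w") as fh:
            fh.write(cfg.to_yaml())

        log.info("stage=%s seed=%d", stage, stage_seed(cfg.seed, stage))
        presets = {"default": DEFAULT_CLASS_SPECS, "hard": HARD_CLASS_SPECS,
                   "table1": DEFAULT_CLASS_SPECS}
        specs = presets[cfg.simulation.preset]
        counts = TABLE1_COUNTS if cfg.simulation.preset == "table1" else None
        segments, y, class_names = generate_segments(
            cfg.simulation.total, seed=stage_seed(cfg.seed, stage),
            class_specs=specs, counts=counts,
            sample_rate=cfg.preprocessing.sample_rate,
            duration_s=cfg.preprocessing.duration_s,
            pre_emphasis=cfg.preprocessing.pre_emphasis)

        stage = "featurize"
        log.info("stage=%s n=%d", stage, len(segments))
        x = featurize_segments(segments, size=cfg.features.image_size,
                               n_fft=cfg.features.n_fft,
                               frame_len_s=cfg.features.frame_len_s,
                               hop_s=cfg.features.hop_s)

        stage = "train"
        log.info("stage=%s folds=%d epochs=%d", stage, cfg.training.folds, cfg.training.epochs)
        net_cfg = NetworkConfig(
            num_classes=cfg.model.num_classes,
            input_size=cfg.features.image_size,
            attention_enabled=cfg.model.attention_enabled,
            attention_position=cfg.model.attention_position,
            cam_hidden_sizes=tuple(cfg.model.cam_hidden_sizes))
        train_cfg = TrainConfig(lr=cfg.training.lr, epochs=cfg.training.epochs,
                                batch_size=cfg.training.batch_size,
                                step_size=cfg.training.step_size,
                                gamma=cfg.training.gamma,
                                seed=stage_seed(cfg.seed, stage))
        plan, histories, oof_pred, oof_proba = cross_validate(
            x, y, k=cfg.training.folds, seed=stage_seed(cfg.seed, "folds"),
            cfg=train_cfg, net_cfg=net_cfg, out_dir=out)
        for i, hist in enumerate(histories):
            hist.to_frame().to_csv(os.path.join(out, f"fold{i}_history.csv"), index=False)

        stage = "evaluate"
        cm = confusion_matrix(y, oof_pred, cfg.model.num_classes, class_names)
        report = metrics_from_confusion(cm)
        fold_of = np.array([plan.assignment[i] for i in range(len(y))])
        per_fold_acc, per_fold_f1 = [], []
        for fold in range(cfg.training.folds):
            m = fold_of == fold
            rep = metrics_from_confusion(
                confusion_matrix(y[m], oof_pred[m], cfg.model.num_classes, class_names))
            per_fold_acc.append(rep.accuracy)
            per_fold_f1.append(rep.macro_f1)
        acc_agg = aggregate_folds(per_fold_acc)
        f1_agg = aggregate_folds(per_fold_f1)
        summary = {
            "overall": report.to_dict(),
            "per_fold_accuracy": per_fold_acc,
            "per_fold_macro_f1": per_fold_f1,
            "accuracy_aggregate": asdict(acc_agg),
            "macro_f1_aggregate": asdict(f1_agg),
            "fold_sizes": plan.fold_sizes(),
            "n_samples": len(y),
        }
        with open(os.path.join(out, "metrics.json"), "w") as fh:
            json.dump(summary, fh, indent=2)
        np.savetxt(os.path.join(out, "confusion_matrix.csv"), cm.counts,
                   fmt="%d", delimiter=",", header=",".join(class_names))
        plot_confusion_matrix(cm, os.path.join(out, "confusion_matrix.png"))

        stage = "noise"
        if cfg.evaluation.noise_snr_db:
            # robustness measured with the last fold's checkpoint on its own
            # held-out validation segments (noise never seen in training)
            last = cfg.training.folds - 1
            mask = fold_of == last
            seg_val = [segments[i] for i in np.nonzero(mask)[0]]
            table = noise_robustness_eval(
                os.path.join(out, f"fold{last}.npz"), seg_val, y[mask],
                cfg.features.image_size, snr_list=cfg.evaluation.noise_snr_db,
                seed=stage_seed(cfg.seed, stage), n_classes=cfg.model.num_classes)
            table.to_csv(os.path.join(out, "noise_table.csv"), index=False)

        manifest = {
            "wall_time_s": round(time.time() - t0, 2),
            "seed": cfg.seed,
            "artifacts": {f: _hash_file(os.path.join(out, f))
                          for f in sorted(os.listdir(out))
                          if os.path.isfile(os.path.join(out, f)) and f != "MANIFEST.json"},
        }
        with open(os.path.join(out, "MANIFEST.json"), "w") as fh:
            json.dump(manifest, fh, indent=2)
        return out
    except Exception as exc:
        failed = os.path.join(out, "failed")
        os.makedirs(failed, exist_ok=True)
        with open(os.path.join(failed, "error.txt"), "w") as fh:
            fh.write(f"stage: {stage}\nerror: {exc!r}\n")
        raise RuntimeError(f"experiment failed in stage {stage!r}") from exc


def run_ablation(cfg: RunConfig) -> dict:
    """Attention-on vs attention-off comparison under identical seeds.

    Returns a dict with one row per model build; the direction of the
    difference is reported, not asserted.
    """
    results = {}
    for name, flag in (("cam_resnet18", True), ("resnet18", False)):
        sub = RunConfig.from_yaml(cfg.to_yaml())
        sub.model.attention_enabled = flag
        sub.out_dir = os.path.join(cfg.out_dir, name)
        run_experiment(sub)
        with open(os.path.join(sub.out_dir, "metrics.json")) as fh:
            m = json.load(fh)
        results[name] = {"accuracy": m["overall"]["accuracy"],
                         "macro_f1": m["overall"]["macro_f1"]}
    results["accuracy_delta"] = (results["cam_resnet18"]["accuracy"]
                                 - results["resnet18"]["accuracy"])
    with open(os.path.join(cfg.out_dir, "ablation.json"), "w") as fh:
        json.dump(results, fh, indent=2)
    return results
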