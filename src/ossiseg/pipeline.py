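"""End-to-end orchestration: simulate -> train both stages -> infer -> evaluate.

This is the desk-scale counterpart of the clinical workflow: a synthetic
cohort replaces the private HRCT dataset, the reduced cascade is trained
from scratch, and the held-out cases are segmented by the full
coarse-to-fine cascade and scored with DSC/ASD/HD/HD95.
"""

from __future__ import annotations

import dataclasses
import os
import time
from dataclasses import asdict

import numpy as np
import pandas as pd

from .config import RunConfig, to_yaml
from .inference import cascade_predict
from .metrics import dsc, evaluate_case, metrics_report
from .phantom import generate_dataset
from .training import TrainConfig, prepare_case, split_dataset, train_model
from .volume_io import ImageVolume, LabelVolume, read_volume


def load_cases(manifest_path: str) -> dict[str, tuple[ImageVolume, LabelVolume]]:
    """Load all image/label pairs listed in a phantom-dataset manifest CSV."""
    manifest = pd.read_csv(manifest_path)
    base = os.path.dirname(os.path.abspath(manifest_path))
    cases = {}
    for _, row in manifest.iterrows():
        img = read_volume(os.path.join(base, row["image_path"]))
        lab = read_volume(os.path.join(base, row["label_path"]), as_labels=True)
        cases[str(row["case_id"])] = (img, lab)
    return cases


def _stage_seed(seed: int, salt: int) -> int:
    return int(np.random.SeedSequence([seed, salt]).generate_state(1)[0] % 2**31)


def train_stage(
    cases: dict[str, tuple[ImageVolume, LabelVolume]],
    train_ids,
    val_ids,
    cfg: TrainConfig,
    net_cfg,
    out_dir: str | None = None,
):
    """Prepare the listed cases at the stage's spacing and train one network."""
    ds = [prepare_case(*cases[i], cfg) for i in train_ids]
    val = [prepare_case(*cases[i], cfg) for i in val_ids] or None
    return train_model(ds, cfg, net_cfg, val_dataset=val, out_dir=out_dir)


def run_demo(cfg: RunConfig, out_dir: str) -> dict:
    """Full desk-scale pipeline; returns a summary dict and writes artifacts.

    Writes the phantom cohort, both stage checkpoints and training logs, a
    per-(case, structure) metrics report, the resolved configuration and a
    summary CSV to ``out_dir``. Held-out cases are the validation + test
    partitions of the seeded 8:1:1 split.
    """
    os.makedirs(out_dir, exist_ok=True)
    to_yaml(cfg, os.path.join(out_dir, "run_config.yaml"))
    timings = {}

    t0 = time.time()
    spec = dataclasses.replace(cfg.phantom, seed=cfg.seed)
    phantom_dir = os.path.join(out_dir, "phantoms")
    generate_dataset(cfg.n_cases, spec, phantom_dir)
    cases = load_cases(os.path.join(phantom_dir, "manifest.csv"))
    timings["simulate_s"] = time.time() - t0

    split = split_dataset(sorted(cases), seed=cfg.seed)
    heldout = list(split.val_ids) + list(split.test_ids)

    t0 = time.time()
    coarse_cfg = dataclasses.replace(cfg.coarse_train, seed=_stage_seed(cfg.seed, 11))
    coarse = train_stage(cases, split.train_ids, split.val_ids, coarse_cfg,
                         cfg.coarse_net, out_dir)
    timings["train_coarse_s"] = time.time() - t0

    t0 = time.time()
    fine_cfg = dataclasses.replace(cfg.fine_train, seed=_stage_seed(cfg.seed, 12))
    fine = train_stage(cases, split.train_ids, split.val_ids, fine_cfg,
                       cfg.fine_net, out_dir)
    timings["train_fine_s"] = time.time() - t0

    t0 = time.time()
    inf = cfg.inference
    case_metrics = {}
    fg_dsc = {}
    for cid in heldout:
        img, lab = cases[cid]
        pred = cascade_predict(
            img,
            coarse.net,
            fine.net,
            coarse_spacing=inf.coarse_spacing,
            fine_spacing=inf.fine_spacing,
            margin_mm=inf.margin_mm,
            tile_size=inf.tile_size,
            threshold=inf.threshold,
            window_level=inf.window_level,
            window_width=inf.window_width,
        )
        case_metrics[cid] = evaluate_case(pred, lab)
        fg_dsc[cid] = dsc(lab.data > 0, pred.data > 0)
    timings["infer_eval_s"] = time.time() - t0

    report = metrics_report(case_metrics)
    report["foreground_dsc"] = report["case_id"].map(fg_dsc)
    report.to_csv(os.path.join(out_dir, "metrics_report.csv"), index=False)

    summary = {
        "n_cases": cfg.n_cases,
        "n_train": len(split.train_ids),
        "n_heldout": len(heldout),
        "heldout_ids": heldout,
        "mean_foreground_dsc": float(np.mean(list(fg_dsc.values()))),
        "per_case_foreground_dsc": {k: float(v) for k, v in fg_dsc.items()},
        "mean_dsc_per_structure": {
            s: float(report[report.structure == s]["dsc"].mean())
            for s in report.structure.unique()
        },
        "coarse_best_epoch": coarse.best_epoch,
        "fine_best_epoch": fine.best_epoch,
        "seed": cfg.seed,
        "timings_s": {k: round(v, 1) for k, v in timings.items()},
    }
    pd.Series(
        {
            "mean_foreground_dsc": summary["mean_foreground_dsc"],
            **{f"dsc_{k}": v for k, v in summary["mean_dsc_per_structure"].items()},
            "seed": cfg.seed,
        }
    ).to_csv(os.path.join(out_dir, "summary.csv"), header=False)
    return summary
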