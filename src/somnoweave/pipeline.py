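"""Umbrella pipeline: simulate -> prepare -> train -> prune -> evaluate ->
explain, with a persisted, resumable run manifest.

All randomness threads from a single run seed through named substreams;
metric files are written deterministically (sorted keys, no timestamps) so
that a rerun with the same config and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np

from ._seeding import child_seed
from .evaluation import evaluate, smoothgrad
from .preprocessing import (
    LabeledDataset,
    Epoch,
    build_dataset,
    epochs_table,
    stratified_split,
)
from .records import LABELS, read_record, write_record
from .simulate import PAPER_CLASS_COUNTS, SimConfig, simulate_dataset
from .sleepnet import (
    SleepNetConfig,
    build_sleepnet,
    count_flops,
    count_params,
    load_checkpoint,
    prune_and_retrain,
    save_checkpoint,
)
from .training import TrainConfig, train

__all__ = ["run_pipeline", "save_epochs", "load_epochs", "STAGES"]

STAGES = ("simulate", "prepare", "train", "prune", "evaluate", "explain")

_ALLOWED_KEYS = {
    "simulate": {"class_counts", "n_subjects", "sim"},
    "prepare": {"window_s", "overlap", "train_frac", "grouped"},
    "train": {f.name for f in dataclasses.fields(TrainConfig)},
    "model": {f.name for f in dataclasses.fields(SleepNetConfig)},
    "prune": {"fraction", "importance", "retrain_epochs"},
    "evaluate": set(),
    "explain": {"n", "noise_sd"},
}


def _check_keys(stage: str, block: dict) -> None:
    unknown = set(block) - _ALLOWED_KEYS[stage]
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} in config section {stage!r}; "
            f"allowed: {sorted(_ALLOWED_KEYS[stage])}"
        )


def _hash_config(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _write_json(path: Path, obj) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


# -- epoch store ------------------------------------------------------------

def save_epochs(dataset: LabeledDataset, out_dir: str | Path) -> Path:
    """Persist a dataset: ``epochs.csv`` metadata + ``epochs.npz`` vectors."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    epochs_table(dataset).to_csv(out_dir / "epochs.csv", index=False)
    X = np.stack([e.values for e in dataset.epochs]) if dataset.epochs else np.empty((0, 0))
    np.savez(out_dir / "epochs.npz", values=X)
    return out_dir


def load_epochs(out_dir: str | Path) -> LabeledDataset:
    out_dir = Path(out_dir)
    import pandas as pd

    table = pd.read_csv(out_dir / "epochs.csv")
    with np.load(out_dir / "epochs.npz") as data:
        X = data["values"]
    if len(table) != len(X):
        raise ValueError("epochs.csv and epochs.npz disagree on epoch count")
    epochs = [
        Epoch(
            values=X[i],
            label=row.label,
            subject_id=row.subject_id,
            record_id=row.record_id,
            window_index=int(row.window_index),
            channel_index=int(row.channel_index),
        )
        for i, row in enumerate(table.itertuples())
    ]
    return LabeledDataset(epochs=epochs, split_assignment=table["split"].tolist())


# -- pipeline ---------------------------------------------------------------

def run_pipeline(
    config: dict,
    out_dir: str | Path,
    seed: int = 0,
    resume: bool = False,
) -> dict:
    """Execute the full pipeline, persisting a stage manifest under out_dir.

    With ``resume=True`` completed stages (matching config hash) are skipped
    and their outputs reused. Returns the manifest dict.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for key in config:
        if key not in set(_ALLOWED_KEYS) | {"model"}:
            raise ValueError(f"unknown top-level config section {key!r}")
    manifest_path = out_dir / "manifest.json"
    manifest = {"seed": int(seed), "stages": []}
    prior = {}
    if resume and manifest_path.exists():
        old = json.loads(manifest_path.read_text())
        if old.get("seed") == seed:
            prior = {s["name"]: s for s in old.get("stages", []) if s["status"] == "ok"}

    def stage_done(name: str, cfg_block: dict, outputs: dict) -> None:
        manifest["stages"].append(
            {
                "name": name,
                "status": "ok",
                "config_hash": _hash_config(cfg_block),
                "outputs": outputs,
                "finished_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
            }
        )
        _write_json(manifest_path, manifest)

    def reusable(name: str, cfg_block: dict) -> bool:
        entry = prior.get(name)
        if entry is None or entry["config_hash"] != _hash_config(cfg_block):
            return False
        return all(Path(p).exists() for p in entry["outputs"].values())

    def reuse(name: str) -> dict:
        entry = dict(prior[name])
        manifest["stages"].append(entry)
        _write_json(manifest_path, manifest)
        return entry["outputs"]

    try:
        # -- simulate -------------------------------------------------------
        blk = dict(config.get("simulate", {}))
        _check_keys("simulate", blk)
        sim_kwargs = blk.get("sim", {})
        counts = blk.get("class_counts", PAPER_CLASS_COUNTS)
        n_subjects = int(blk.get("n_subjects", 5))
        rec_dir = out_dir / "records"
        if reusable("simulate", blk):
            outputs = reuse("simulate")
            records = [read_record(p) for p in sorted(Path(rec_dir).iterdir())]
        else:
            cfg = SimConfig(**sim_kwargs)
            records, sim_manifest = simulate_dataset(
                counts, cfg, n_subjects=n_subjects, seed=child_seed(seed, "simulate")
            )
            for rec, entry in zip(records, sim_manifest["records"]):
                write_record(rec, rec_dir / rec.record_id)
                entry["path"] = str(rec_dir / rec.record_id)
            _write_json(out_dir / "sim_manifest.json", _jsonable(sim_manifest))
            stage_done("simulate", blk, {"records": str(rec_dir)})

        # -- prepare --------------------------------------------------------
        blk = dict(config.get("prepare", {}))
        _check_keys("prepare", blk)
        ep_dir = out_dir / "epochs"
        if reusable("prepare", blk):
            reuse("prepare")
            dataset = load_epochs(ep_dir)
        else:
            dataset = build_dataset(
                records,
                window_s=float(blk.get("window_s", 10.0)),
                overlap=float(blk.get("overlap", 0.5)),
            )
            dataset = stratified_split(
                dataset,
                train_frac=float(blk.get("train_frac", 0.9)),
                seed=child_seed(seed, "split"),
                grouped=bool(blk.get("grouped", False)),
            )
            save_epochs(dataset, ep_dir)
            stage_done("prepare", blk, {"epochs": str(ep_dir)})

        # -- train ----------------------------------------------------------
        mblk = dict(config.get("model", {}))
        _check_keys("model", mblk)
        tblk = dict(config.get("train", {}))
        _check_keys("train", tblk)
        ckpt = out_dir / "sleepnet.npz"
        both = {"model": mblk, "train": tblk}
        if reusable("train", both):
            reuse("train")
            model = load_checkpoint(ckpt)
        else:
            mcfg = SleepNetConfig(**{**mblk, "seed": child_seed(seed, "init")})
            tcfg = TrainConfig(**{**tblk, "seed": child_seed(seed, "train")})
            model = build_sleepnet(mcfg)
            model, history = train(model, dataset, tcfg)
            save_checkpoint(model, ckpt)
            _write_json(out_dir / "train_history.json", _jsonable(history))
            stage_done("train", both, {"checkpoint": str(ckpt)})

        # -- prune ----------------------------------------------------------
        blk = dict(config.get("prune", {}))
        _check_keys("prune", blk)
        pruned_ckpt = out_dir / "sleepnet_pruned.npz"
        if reusable("prune", blk):
            reuse("prune")
            pruned = load_checkpoint(pruned_ckpt)
        else:
            retrain_cfg = TrainConfig(
                max_epochs=int(blk.get("retrain_epochs", 3)),
                seed=child_seed(seed, "retrain"),
            )
            pruned, report = prune_and_retrain(
                model,
                dataset,
                fraction=float(blk.get("fraction", 0.5)),
                importance=blk.get("importance", "filter-l1"),
                train_cfg=retrain_cfg,
            )
            save_checkpoint(pruned, pruned_ckpt)
            _write_json(out_dir / "prune_report.json", _jsonable(report.to_dict()))
            stage_done("prune", blk, {"checkpoint": str(pruned_ckpt)})

        # -- evaluate -------------------------------------------------------
        blk = dict(config.get("evaluate", {}))
        _check_keys("evaluate", blk)
        metrics_path = out_dir / "metrics.json"
        if reusable("evaluate", blk):
            reuse("evaluate")
        else:
            Xva, yva = dataset.arrays("val")
            report = evaluate(pruned, Xva, yva)
            metrics = report.to_dict()
            metrics["params"] = count_params(pruned)
            metrics["flops"] = count_flops(pruned)
            _write_json(metrics_path, metrics)
            stage_done("evaluate", blk, {"metrics": str(metrics_path)})

        # -- explain --------------------------------------------------------
        blk = dict(config.get("explain", {}))
        _check_keys("explain", blk)
        sal_path = out_dir / "saliency.json"
        if reusable("explain", blk):
            reuse("explain")
        else:
            sal = {}
            val_idx = dataset.indices("val")
            for c, lab in enumerate(LABELS):
                match = [i for i in val_idx if dataset.epochs[i].label == lab]
                if not match:
                    continue
                ep = dataset.epochs[match[0]]
                m = smoothgrad(
                    pruned,
                    ep.values,
                    target_class=c,
                    n=int(blk.get("n", 25)),
                    noise_sd=blk.get("noise_sd"),
                    seed=child_seed(seed, f"saliency/{lab}"),
                )
                sal[lab] = {
                    "epoch": f"{ep.record_id}/{ep.window_index}",
                    "abs_mean": float(np.abs(m.contributions).mean()),
                    "top_decile_start_s": _top_decile(m.contributions),
                }
            _write_json(sal_path, sal)
            stage_done("explain", blk, {"saliency": str(sal_path)})
    except Exception:
        manifest["stages"].append(
            {"name": "failed", "status": "error", "at": time.strftime("%Y-%m-%dT%H:%M:%S")}
        )
        _write_json(manifest_path, manifest)
        raise
    return manifest


def _top_decile(contrib: np.ndarray, fs: float = 100.0) -> list:
    k = max(len(contrib) // 10, 1)
    idx = np.sort(np.argsort(np.abs(contrib))[::-1][:k])
    return [float(idx[0] / fs), float(idx[-1] / fs)]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
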