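"""Training, random hyperparameter search, and few-shot transfer learning.

Everything is seeded: initialization, minibatch order, search-trial
sampling and shot selection all flow from explicit seeds, so reruns with
identical configs reproduce metrics.
"""

from __future__ import annotations

import dataclasses
import time
from dataclasses import dataclass, replace

import numpy as np

from ._seeding import child_seed, substream
from .nn import Adam, softmax_cross_entropy
from .nn import core as nn_core
from .preprocessing import LabeledDataset
from .records import LABELS
from .sleepnet import SleepNet, SleepNetConfig

__all__ = [
    "TrainConfig",
    "TrialRecord",
    "train",
    "random_search",
    "few_shot_transfer",
    "clone_model",
]


@dataclass
class TrainConfig:
    optimizer: str = "adam"
    lr: float = 3e-3
    batch_size: int = 64
    max_epochs: int = 12
    patience: int = 6            # early stopping on validation accuracy
    weight_decay: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")


def clone_model(model: SleepNet) -> SleepNet:
    out = SleepNet(model.cfg)
    out.load_state_arrays(model.state_arrays())
    return out


def _accuracy(model: SleepNet, X: np.ndarray, y: np.ndarray) -> float:
    if len(y) == 0:
        return float("nan")
    return float(np.mean(model.predict(X) == y))


def train(
    model: SleepNet,
    dataset: LabeledDataset,
    cfg: TrainConfig | None = None,
    train_split: str = "train",
    val_split: str = "val",
):
    """Minibatch Adam training with early stopping on validation accuracy.

    Returns ``(best_model, history)`` where ``history`` has per-epoch train
    loss/accuracy and validation accuracy; the returned model carries the
    weights of the best validation epoch.
    """
    cfg = cfg or TrainConfig()
    Xtr, ytr = dataset.arrays(train_split)
    if len(ytr) == 0:
        raise ValueError(f"empty training split {train_split!r}")
    Xva, yva = dataset.arrays(val_split)
    has_val = len(yva) > 0
    Xtr = np.asarray(Xtr, dtype=nn_core.DTYPE)
    rng = substream(cfg.seed, "train/batches")
    opt = Adam(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    history = {"train_loss": [], "train_accuracy": [], "val_accuracy": []}
    best_acc, best_state, best_epoch = -np.inf, None, -1
    n = len(ytr)
    t0 = time.time()
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        losses, hits = [], 0
        for i in range(0, n, cfg.batch_size):
            idx = order[i: i + cfg.batch_size]
            logits = model.forward(Xtr[idx], train=True)
            loss, grad, probs = softmax_cross_entropy(logits, ytr[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}, step {i // cfg.batch_size}: "
                    f"loss={loss}, lr={cfg.lr}"
                )
            opt.zero_grad()
            model.backward(grad)
            opt.step()
            losses.append(loss)
            hits += int(np.sum(probs.argmax(axis=1) == ytr[idx]))
        tr_acc = hits / n
        va_acc = _accuracy(model, Xva, yva) if has_val else tr_acc
        history["train_loss"].append(float(np.mean(losses)))
        history["train_accuracy"].append(float(tr_acc))
        history["val_accuracy"].append(float(va_acc) if has_val else None)
        if va_acc > best_acc:
            best_acc, best_epoch = va_acc, epoch
            best_state = {k: v.copy() for k, v in model.state_arrays().items()}
        elif epoch - best_epoch >= cfg.patience:
            break
    if best_state is not None:
        model.load_state_arrays(best_state)
    history["best_epoch"] = best_epoch
    history["best_val_accuracy"] = float(best_acc)
    history["wall_time_s"] = time.time() - t0
    return model, history


# --------------------------------------------------------------------------
# random hyperparameter search
# --------------------------------------------------------------------------

@dataclass
class TrialRecord:
    hyperparameters: dict
    val_accuracy: float
    n_steps: int
    seed: int


_MODEL_FIELDS = {f.name for f in dataclasses.fields(SleepNetConfig)}
_TRAIN_FIELDS = {f.name for f in dataclasses.fields(TrainConfig)}


def _sample_value(spec, rng: np.random.Generator):
    if isinstance(spec, list):
        return spec[int(rng.integers(len(spec)))]
    if isinstance(spec, tuple):
        if len(spec) == 3 and spec[2] == "log":
            lo, hi = float(spec[0]), float(spec[1])
            if not 0 < lo <= hi:
                raise ValueError(f"invalid log range {spec}")
            return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        lo, hi = spec[0], spec[1]
        if lo > hi:
            raise ValueError(f"invalid range {spec}")
        if isinstance(lo, int) and isinstance(hi, int):
            return int(rng.integers(lo, hi + 1))
        return float(rng.uniform(lo, hi))
    raise ValueError(f"cannot interpret search-space entry {spec!r}")


def default_search_space() -> dict:
    """Ranges for the hyperparameters the model is sensitive to."""
    return {
        "lr": (1e-4, 1e-2, "log"),
        "lstm_hidden": [16, 32],
        "n_heads": [2, 4],
        "d_ff": [32, 64],
        "resnet_channels": [(32, 64, 64), (64, 128, 128)],
    }


def random_search(
    space: dict,
    n_trials: int,
    dataset: LabeledDataset,
    base_model_cfg: SleepNetConfig | None = None,
    base_train_cfg: TrainConfig | None = None,
    seed: int = 0,
) -> list[TrialRecord]:
    """Independent seeded trials over a declared hyperparameter space."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    base_model_cfg = base_model_cfg or SleepNetConfig()
    base_train_cfg = base_train_cfg or TrainConfig(max_epochs=4)
    records = []
    for trial in range(n_trials):
        trial_seed = child_seed(seed, f"search/{trial}")
        rng = np.random.default_rng(trial_seed)
        sampled = {k: _sample_value(v, rng) for k, v in space.items()}
        model_kw = {k: v for k, v in sampled.items() if k in _MODEL_FIELDS}
        train_kw = {k: v for k, v in sampled.items() if k in _TRAIN_FIELDS}
        unknown = set(sampled) - _MODEL_FIELDS - _TRAIN_FIELDS
        if unknown:
            raise ValueError(f"unknown hyperparameter(s) in space: {sorted(unknown)}")
        mcfg = replace(base_model_cfg, seed=trial_seed, **model_kw)
        tcfg = replace(base_train_cfg, seed=trial_seed, **train_kw)
        model = SleepNet(mcfg)
        model, hist = train(model, dataset, tcfg)
        n_steps = len(hist["train_loss"]) * int(
            np.ceil(dataset.indices("train").size / tcfg.batch_size)
        )
        records.append(
            TrialRecord(
                hyperparameters=sampled,
                val_accuracy=hist["best_val_accuracy"],
                n_steps=n_steps,
                seed=trial_seed,
            )
        )
    return records


def robustness_summary(trials: list[TrialRecord], threshold: float = 0.9) -> dict:
    accs = np.array([t.val_accuracy for t in trials])
    return {
        "n_trials": len(trials),
        "threshold": threshold,
        "fraction_above": float(np.mean(accs > threshold)) if len(accs) else 0.0,
        "best": float(accs.max()) if len(accs) else float("nan"),
        "median": float(np.median(accs)) if len(accs) else float("nan"),
    }


# --------------------------------------------------------------------------
# few-shot transfer
# --------------------------------------------------------------------------

@dataclass
class TransferReport:
    finetuned_accuracy: float
    scratch_accuracy: float
    zero_shot_accuracy: float
    gap: float
    shots: int
    n_test: int
    valid: bool
    notes: str = ""

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def few_shot_transfer(
    pretrained: SleepNet,
    target_dataset: LabeledDataset,
    shots: int = 15,
    cfg: TrainConfig | None = None,
    seed: int = 0,
    pretrain_subjects=None,
    finetune_lr_scale: float = 0.1,
    head_only: bool = False,
) -> TransferReport:
    """Few-shot adaptation to a new wearer, with a from-scratch control.

    Takes ``shots`` epochs per class from the target subject for adaptation,
    fine-tunes all weights of the pretrained model at a reduced learning
    rate (or only the head with ``head_only``), trains an identically
    configured fresh model on the same shots, and evaluates both on the
    remaining target epochs.
    """
    cfg = cfg or TrainConfig(max_epochs=30, patience=30, batch_size=16)
    target_subjects = {e.subject_id for e in target_dataset.epochs}
    if pretrain_subjects is not None:
        overlap = target_subjects & set(pretrain_subjects)
        if overlap:
            raise ValueError(
                f"target subject(s) {sorted(overlap)} present in pretraining manifest; "
                "transfer evaluation would leak"
            )
    rng = substream(seed, "transfer/shots")
    labels = np.array([e.label for e in target_dataset.epochs])
    shot_idx: list[int] = []
    for lab in LABELS:
        idx = np.flatnonzero(labels == lab)
        if idx.size == 0:
            continue
        if idx.size < shots:
            raise ValueError(
                f"target subject has only {idx.size} {lab!r} epochs; need {shots} shots"
            )
        shot_idx.extend(idx[rng.permutation(idx.size)[:shots]].tolist())
    shot_set = set(shot_idx)
    test_idx = [i for i in range(len(labels)) if i not in shot_set]
    valid = len(test_idx) > 0
    notes = "" if valid else "shots cover the entire target set; resubstitution accuracy"

    assignment = ["test"] * len(labels)
    for i in shot_idx:
        assignment[i] = "train"
    shot_ds = LabeledDataset(target_dataset.epochs, assignment)
    eval_idx = test_idx if valid else shot_idx
    Xte = np.stack([target_dataset.epochs[i].values for i in eval_idx])
    yte = np.array([target_dataset.epochs[i].label_index for i in eval_idx])

    zero_shot = float(np.mean(pretrained.predict(Xte) == yte))

    ft = clone_model(pretrained)
    ft_cfg = replace(cfg, lr=cfg.lr * finetune_lr_scale, seed=child_seed(seed, "transfer/ft"))
    if head_only:
        head_params = ft.head.parameters()
        opt_params = head_params
        _train_on(ft, shot_ds, ft_cfg, params=opt_params)
    else:
        ft, _ = train(ft, shot_ds, ft_cfg, val_split="__none__")
    ft_acc = float(np.mean(ft.predict(Xte) == yte))

    scratch = SleepNet(replace(pretrained.cfg, seed=child_seed(seed, "transfer/scratch")))
    scratch, _ = train(
        scratch, shot_ds, replace(cfg, seed=child_seed(seed, "transfer/scratch-train")),
        val_split="__none__",
    )
    sc_acc = float(np.mean(scratch.predict(Xte) == yte))

    return TransferReport(
        finetuned_accuracy=ft_acc,
        scratch_accuracy=sc_acc,
        zero_shot_accuracy=zero_shot,
        gap=ft_acc - sc_acc,
        shots=shots,
        n_test=len(test_idx),
        valid=valid,
        notes=notes,
    )


def _train_on(model: SleepNet, dataset: LabeledDataset, cfg: TrainConfig, params) -> None:
    """Head-only fine-tuning loop (subset of parameters)."""
    X, y = dataset.arrays("train")
    X = np.asarray(X, dtype=nn_core.DTYPE)
    rng = substream(cfg.seed, "train/batches")
    opt = Adam(params, lr=cfg.lr)
    for _ in range(cfg.max_epochs):
        order = rng.permutation(len(y))
        for i in range(0, len(y), cfg.batch_size):
            idx = order[i: i + cfg.batch_size]
            logits = model.forward(X[idx], train=True)
            loss, grad, _ = softmax_cross_entropy(logits, y[idx])
            if not np.isfinite(loss):
                raise RuntimeError("head-only fine-tuning diverged")
            model.zero_grad()
            model.backward(grad)
            opt.step()
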