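"""SleepNet: residual BiLSTM positional encoding, multi-head self-attention,
and a 1-D ResNet feature extractor, ending in a 6-way softmax head.

The signal path is::

    (N, 1000) raw epoch
      -> strided Conv1d patch projection        (N, d_model, L_tokens)
      -> residual BiLSTM positional encoder     x = proj + W_l * BiLSTM(proj)
      -> N post-norm self-attention blocks
      -> 1-D ResNet stack (two convs + projection shortcut per block)
      -> global average pooling                 (N, C_last)  [the embedding]
      -> affine head -> softmax                 (N, 6)

Profiling uses a fixed convention: FLOPs = 2 x multiply-accumulates of the
matrix/convolution products of one forward pass (normalizations, activations
and softmaxes are not counted). Structured pruning removes whole ResNet
convolution output channels ("nodes") ranked by filter L1 norm, per layer,
with dependency-consistent rewiring of downstream shapes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from . import nn
from .nn import core as nn_core

__all__ = [
    "SleepNetConfig",
    "SleepNet",
    "PruneReport",
    "build_sleepnet",
    "count_params",
    "count_flops",
    "prune_sleepnet",
    "prune_and_retrain",
    "extract_features",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class SleepNetConfig:
    """Architecture hyperparameters.

    The default widths are chosen so the pruned model profiles well under
    5 M parameters and 0.5 GFLOPs at input length 1000, the budget for
    edge deployment.
    """

    input_len: int = 1000
    n_classes: int = 6
    # patch projection (input projection of the residual encoder)
    proj_kernel: int = 21
    proj_stride: int = 10
    d_model: int = 32
    # residual BiLSTM positional encoder
    lstm_hidden: int = 32
    # self-attention
    n_attn_blocks: int = 2
    n_heads: int = 4
    d_ff: int = 64
    dropout: float = 0.1
    # 1-D ResNet
    resnet_channels: tuple = (64, 128, 128)
    resnet_kernel: int = 7
    resnet_strides: tuple = (2, 2, 1)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        if self.n_classes != 6:
            raise ValueError("SleepNet classifies exactly 6 sleep states")
        if len(self.resnet_channels) != len(self.resnet_strides):
            raise ValueError("resnet_channels and resnet_strides must align")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SleepNetConfig":
        d = json.loads(text)
        d["resnet_channels"] = tuple(d["resnet_channels"])
        d["resnet_strides"] = tuple(d["resnet_strides"])
        return cls(**d)


class ResBlock(nn.Module):
    """conv-bn-relu-conv-bn plus a 1x1 projection shortcut, then ReLU.

    A projection shortcut is used even when shapes match so that channel
    pruning can rewire every block uniformly.
    """

    def __init__(self, c_in, c_out, kernel, stride, rng):
        self.conv1 = nn.Conv1d(c_in, c_out, kernel, rng, stride=stride)
        self.bn1 = nn.BatchNorm1d(c_out)
        self.relu1 = nn.ReLU()
        self.conv2 = nn.Conv1d(c_out, c_out, kernel, rng, stride=1)
        self.bn2 = nn.BatchNorm1d(c_out)
        self.skip = nn.Conv1d(c_in, c_out, 1, rng, stride=stride, padding=0)
        self.bns = nn.BatchNorm1d(c_out)
        self.relu2 = nn.ReLU()

    def forward(self, x, train: bool = False):
        main = self.bn2(self.conv2(self.relu1(self.bn1(self.conv1(x, train=train), train=train), train=train), train=train), train=train)
        sc = self.bns(self.skip(x, train=train), train=train)
        return self.relu2(main + sc, train=train)

    def backward(self, grad):
        g = self.relu2.backward(grad)
        gm = self.conv1.backward(self.bn1.backward(self.relu1.backward(self.conv2.backward(self.bn2.backward(g)))))
        gs = self.skip.backward(self.bns.backward(g))
        return gm + gs


class SleepNet(nn.Module):
    def __init__(self, cfg: SleepNetConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        d = cfg.d_model
        self.input_proj = nn.Conv1d(
            1, d, cfg.proj_kernel, rng, stride=cfg.proj_stride
        )
        self.bilstm = nn.BiLSTM(d, cfg.lstm_hidden, rng)
        self.lstm_proj = nn.Dense(2 * cfg.lstm_hidden, d, rng)
        self.blocks = [
            nn.TransformerBlock(d, cfg.n_heads, cfg.d_ff, rng, cfg.dropout)
            for _ in range(cfg.n_attn_blocks)
        ]
        self.resnet = []
        c_prev = d
        for c, s in zip(cfg.resnet_channels, cfg.resnet_strides):
            self.resnet.append(ResBlock(c_prev, c, cfg.resnet_kernel, s, rng))
            c_prev = c
        self.pool = nn.GlobalAvgPool()
        self.head = nn.Dense(c_prev, cfg.n_classes, rng)

    # -- forward / backward --------------------------------------------------
    def forward(self, x, train: bool = False, return_features: bool = False):
        x = np.asarray(x, dtype=nn_core.DTYPE)
        if x.ndim == 1:
            x = x[None, :]
        if x.shape[-1] != self.cfg.input_len:
            raise ValueError(
                f"input length {x.shape[-1]} != configured {self.cfg.input_len}"
            )
        z = self.input_proj(x[:, None, :], train=train)      # (N, d, Lt)
        p = np.ascontiguousarray(z.transpose(0, 2, 1))        # (N, Lt, d)
        enc = p + self.lstm_proj(self.bilstm(p, train=train), train=train)
        for blk in self.blocks:
            enc = blk(enc, train=train)
        h = np.ascontiguousarray(enc.transpose(0, 2, 1))      # (N, d, Lt)
        for rb in self.resnet:
            h = rb(h, train=train)
        feats = self.pool(h, train=train)
        if return_features:
            return feats
        return self.head(feats, train=train)

    def backward(self, grad_logits):
        g = self.head.backward(grad_logits)
        g = self.pool.backward(g)
        for rb in reversed(self.resnet):
            g = rb.backward(g)
        g = np.ascontiguousarray(g.transpose(0, 2, 1))
        for blk in reversed(self.blocks):
            g = blk.backward(g)
        gp = g + self.bilstm.backward(self.lstm_proj.backward(g))
        gz = np.ascontiguousarray(gp.transpose(0, 2, 1))
        gx = self.input_proj.backward(gz)
        return gx[:, 0, :]

    # -- inference helpers ----------------------------------------------------
    def predict_proba(self, x, batch_size: int = 64) -> np.ndarray:
        x = np.asarray(x, dtype=nn_core.DTYPE)
        if x.ndim == 1:
            x = x[None, :]
        out = [
            nn.softmax(self.forward(x[i: i + batch_size]))
            for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(out, axis=0)

    def predict(self, x, batch_size: int = 64) -> np.ndarray:
        return self.predict_proba(x, batch_size=batch_size).argmax(axis=1)

    def input_gradient(self, x, target_class: int) -> np.ndarray:
        """d(logit of target class) / d(input), in eval mode."""
        x = np.asarray(x, dtype=nn_core.DTYPE)
        squeeze = x.ndim == 1
        logits = self.forward(x, train=False)
        g = np.zeros_like(logits)
        g[:, int(target_class)] = 1.0
        gx = self.backward(g)
        return gx[0] if squeeze else gx

    # -- profiling ------------------------------------------------------------
    def macs(self, input_len: int | None = None) -> int:
        """Multiply-accumulates of one single-sample forward pass."""
        cfg = self.cfg
        L0 = cfg.input_len if input_len is None else int(input_len)
        total = 0
        lt = self.input_proj.out_len(L0)
        total += lt * self.input_proj.c_out * self.input_proj.c_in * self.input_proj.kernel
        d = cfg.d_model
        H = cfg.lstm_hidden
        total += 2 * lt * 4 * H * (d + H)              # two LSTM directions
        total += lt * (2 * H) * d                      # lstm output projection
        dh = d // cfg.n_heads
        for _ in self.blocks:
            total += 4 * lt * d * d                    # Q, K, V, O projections
            total += 2 * lt * lt * cfg.n_heads * dh    # scores + context
            total += 2 * lt * d * cfg.d_ff             # feed-forward pair
        l_in = lt
        for rb in self.resnet:
            l1 = rb.conv1.out_len(l_in)
            total += l1 * rb.conv1.c_out * rb.conv1.c_in * rb.conv1.kernel
            l2 = rb.conv2.out_len(l1)
            total += l2 * rb.conv2.c_out * rb.conv2.c_in * rb.conv2.kernel
            ls = rb.skip.out_len(l_in)
            total += ls * rb.skip.c_out * rb.skip.c_in * rb.skip.kernel
            l_in = l2
        total += self.head.W.data.shape[0] * self.head.W.data.shape[1]
        return int(total)


def build_sleepnet(cfg: SleepNetConfig | None = None) -> SleepNet:
    return SleepNet(cfg or SleepNetConfig())


def count_params(model: nn.Module) -> int:
    """Number of trainable scalars."""
    return model.n_params()


def count_flops(model: SleepNet, input_len: int | None = None) -> int:
    """Forward-pass FLOPs at ``input_len``, as 2 x multiply-accumulates."""
    return 2 * model.macs(input_len)


# --------------------------------------------------------------------------
# structured pruning
# --------------------------------------------------------------------------

@dataclass
class PruneReport:
    params_before: int
    params_after: int
    flops_before: int
    flops_after: int
    fraction_pruned: float
    importance_metric: str = "filter-l1"
    accuracy_before: float = float("nan")
    accuracy_after: float = float("nan")

    @property
    def flops_reduction(self) -> float:
        return 1.0 - self.flops_after / self.flops_before

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["flops_reduction"] = self.flops_reduction
        return d


def _keep_count(channels: int, fraction: float) -> int:
    keep = channels - int(np.floor(channels * fraction))
    if keep < 1:
        raise ValueError(
            f"pruning fraction {fraction} would remove all {channels} channels of a layer"
        )
    return keep


def _filter_l1(weight: np.ndarray) -> np.ndarray:
    return np.abs(weight).sum(axis=(1, 2))


def prune_sleepnet(
    model: SleepNet, fraction: float = 0.5, importance: str = "filter-l1"
) -> SleepNet:
    """Channel-prune the ResNet stack, returning a rewired copy.

    Output channels of each convolution are ranked by the L1 norm of their
    filters; the lowest ``fraction`` per layer is removed. Both the internal
    (conv1) and block-output (conv2 + shortcut) channel sets shrink, and the
    classifier head's input features follow the last block.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    if importance != "filter-l1":
        raise ValueError(f"unknown importance metric {importance!r}")
    cfg = model.cfg
    new_channels = tuple(
        _keep_count(c, fraction) for c in cfg.resnet_channels
    )
    pruned = SleepNet(replace(cfg, resnet_channels=new_channels))

    # encoder and attention stacks are untouched: copy verbatim
    for dst, src in [
        (pruned.input_proj, model.input_proj),
        (pruned.bilstm, model.bilstm),
        (pruned.lstm_proj, model.lstm_proj),
    ]:
        for pd, ps in zip(dst.parameters(), src.parameters()):
            pd.data = ps.data.copy()
    for bd, bs in zip(pruned.blocks, model.blocks):
        for pd, ps in zip(bd.parameters(), bs.parameters()):
            pd.data = ps.data.copy()

    prev_keep = np.arange(cfg.d_model)
    for rb_new, rb_old, c_old in zip(pruned.resnet, model.resnet, cfg.resnet_channels):
        k = _keep_count(c_old, fraction)
        imp_mid = _filter_l1(rb_old.conv1.W.data)
        keep_mid = np.sort(np.argsort(imp_mid)[::-1][:k])
        imp_out = _filter_l1(rb_old.conv2.W.data) + _filter_l1(rb_old.skip.W.data)
        keep_out = np.sort(np.argsort(imp_out)[::-1][:k])

        rb_new.conv1.W.data = rb_old.conv1.W.data[keep_mid][:, prev_keep, :].copy()
        rb_new.conv1.b.data = rb_old.conv1.b.data[keep_mid].copy()
        _slice_bn(rb_new.bn1, rb_old.bn1, keep_mid)
        rb_new.conv2.W.data = rb_old.conv2.W.data[keep_out][:, keep_mid, :].copy()
        rb_new.conv2.b.data = rb_old.conv2.b.data[keep_out].copy()
        _slice_bn(rb_new.bn2, rb_old.bn2, keep_out)
        rb_new.skip.W.data = rb_old.skip.W.data[keep_out][:, prev_keep, :].copy()
        rb_new.skip.b.data = rb_old.skip.b.data[keep_out].copy()
        _slice_bn(rb_new.bns, rb_old.bns, keep_out)
        prev_keep = keep_out

    pruned.head.W.data = model.head.W.data[prev_keep].copy()
    pruned.head.b.data = model.head.b.data.copy()
    for p in pruned.parameters():
        p.grad = np.zeros_like(p.data)
    return pruned


def _slice_bn(dst: nn.BatchNorm1d, src: nn.BatchNorm1d, keep: np.ndarray) -> None:
    dst.gamma.data = src.gamma.data[keep].copy()
    dst.beta.data = src.beta.data[keep].copy()
    dst.running_mean = src.running_mean[keep].copy()
    dst.running_var = src.running_var[keep].copy()


def prune_and_retrain(
    model: SleepNet,
    dataset=None,
    fraction: float = 0.5,
    importance: str = "filter-l1",
    train_cfg=None,
    eval_split: str = "val",
):
    """Prune the ResNet stack and (optionally) retrain on a dataset.

    ``dataset`` is a :class:`~somnoweave.preprocessing.LabeledDataset`; when
    omitted the function only rewires and profiles (useful for architecture
    studies). Returns ``(pruned_model, PruneReport)``.
    """
    from .evaluation import evaluate  # local import: avoids a module cycle
    from .training import TrainConfig, train

    params_before = count_params(model)
    flops_before = count_flops(model)
    acc_before = float("nan")
    if dataset is not None and dataset.indices(eval_split).size:
        Xe, ye = dataset.arrays(eval_split)
        acc_before = evaluate(model, Xe, ye).overall_accuracy
    pruned = prune_sleepnet(model, fraction=fraction, importance=importance)
    acc_after = float("nan")
    if dataset is not None and fraction > 0:
        cfg = train_cfg or TrainConfig(max_epochs=3)
        pruned, _ = train(pruned, dataset, cfg)
    if dataset is not None and dataset.indices(eval_split).size:
        Xe, ye = dataset.arrays(eval_split)
        acc_after = evaluate(pruned, Xe, ye).overall_accuracy
    report = PruneReport(
        params_before=params_before,
        params_after=count_params(pruned),
        flops_before=flops_before,
        flops_after=count_flops(pruned),
        fraction_pruned=fraction,
        importance_metric=importance,
        accuracy_before=acc_before,
        accuracy_after=acc_after,
    )
    return pruned, report


def extract_features(model: SleepNet, batch: np.ndarray) -> np.ndarray:
    """Penultimate (pooled) embeddings, deterministic in eval mode."""
    batch = np.asarray(batch, dtype=nn_core.DTYPE)
    if batch.ndim == 1:
        batch = batch[None, :]
    out = []
    for i in range(0, len(batch), 64):
        out.append(model.forward(batch[i: i + 64], return_features=True))
    return np.concatenate(out, axis=0)


# --------------------------------------------------------------------------
# checkpoints
# --------------------------------------------------------------------------

_CKPT_VERSION = 1


def save_checkpoint(model: SleepNet, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = model.state_arrays()
    meta = np.array(
        json.dumps({"version": _CKPT_VERSION, "config": json.loads(model.cfg.to_json())})
    )
    np.savez(path, __meta__=meta, **arrays)
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_checkpoint(path: str | Path) -> SleepNet:
    path = Path(path)
    if not path.exists() and path.with_suffix(path.suffix + ".npz").exists():
        path = path.with_suffix(path.suffix + ".npz")
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        if meta.get("version") != _CKPT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta.get('version')}")
        cfg = SleepNetConfig.from_json(json.dumps(meta["config"]))
        model = SleepNet(cfg)
        model.load_state_arrays({k: data[k] for k in data.files if k != "__meta__"})
    return model
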