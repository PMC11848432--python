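"""Preprocessing: records -> normalized labeled single-channel epochs.

The pipeline mirrors the acquisition-side processing of the garment study:
10-s windows with 50% overlap segmented from annotated sessions, the channel
with the highest band-limited power density selected as the representative
input, Z-score normalization per epoch, and proportional (stratified) random
splitting into train/validation with an optional record-grouped mode that
rules out overlap leakage across splits.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seeding import substream
from .records import LABELS, LABEL_TO_INDEX, MultichannelRecord

logger = logging.getLogger(__name__)

__all__ = [
    "Epoch",
    "LabeledDataset",
    "segment",
    "select_strongest_channel",
    "zscore",
    "stratified_split",
    "channel_correlation",
    "build_dataset",
    "summary_features",
]

_SD_GUARD = 1e-8
_BAND = (0.05, 10.0)  # informative laryngeal-vibration band, Hz


@dataclass
class Epoch:
    """One fixed-length labeled single-channel training sample."""

    values: np.ndarray
    label: str
    subject_id: str
    record_id: str
    window_index: int
    channel_index: int

    @property
    def label_index(self) -> int:
        return LABEL_TO_INDEX[self.label]


@dataclass
class LabeledDataset:
    """Epochs plus a train/val(/test) split assignment."""

    epochs: list[Epoch]
    split_assignment: list[str] = field(default_factory=list)  # per-epoch
    provenance: dict = field(default_factory=dict)

    def indices(self, split: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.split_assignment) == split)

    def subset(self, split: str) -> list[Epoch]:
        return [self.epochs[i] for i in self.indices(split)]

    def arrays(self, split: str | None = None):
        """(X, y) arrays; y uses canonical label indices."""
        eps = self.epochs if split is None else self.subset(split)
        X = np.stack([e.values for e in eps]) if eps else np.empty((0, 0))
        y = np.array([e.label_index for e in eps], dtype=int)
        return X, y

    def class_counts(self, split: str | None = None) -> dict:
        eps = self.epochs if split is None else self.subset(split)
        out = {lab: 0 for lab in LABELS}
        for e in eps:
            out[e.label] += 1
        return out


# --------------------------------------------------------------------------

def segment(
    record: MultichannelRecord,
    window_s: float = 10.0,
    overlap: float = 0.5,
):
    """Slice a record into labeled multichannel windows.

    Windows start every ``window_s * (1 - overlap)`` seconds. A window keeps
    a label only when a single annotation covers it entirely; uncovered or
    label-straddling windows are dropped, mirroring the study's filtering of
    unlabelable segments.

    Returns a list of ``(window 6xW array, label, window_index)`` tuples.
    """
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    w = window_s * record.fs
    if abs(w - round(w)) > 1e-9:
        raise ValueError(f"window_s * fs must be integral, got {w}")
    w = int(round(w))
    hop = window_s * (1.0 - overlap) * record.fs
    if abs(hop - round(hop)) > 1e-9:
        raise ValueError("hop length (window_s * (1 - overlap) * fs) must be integral")
    hop = int(round(hop))
    out = []
    n = record.n_samples
    idx = 0
    for start in range(0, n - w + 1, hop):
        t0 = start / record.fs
        t1 = (start + w) / record.fs
        label = None
        for a0, a1, lab in record.annotations:
            if a0 - 1e-9 <= t0 and t1 <= a1 + 1e-9:
                label = lab
                break
        if label is not None:
            out.append((record.values[:, start: start + w], label, idx))
        idx += 1
    return out


def _band_power(x: np.ndarray, fs: float, band=_BAND) -> np.ndarray:
    """Mean power per channel restricted to ``band`` after mean removal."""
    x = x - x.mean(axis=-1, keepdims=True)
    spec = np.abs(np.fft.rfft(x, axis=-1)) ** 2
    freqs = np.fft.rfftfreq(x.shape[-1], d=1.0 / fs)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    return spec[..., mask].sum(axis=-1) / x.shape[-1]


def select_strongest_channel(window: np.ndarray, fs: float = 100.0) -> int:
    """Index of the channel with the highest band-limited power density.

    Ties break toward the lowest index; an all-constant window logs a
    warning and returns channel 0.
    """
    window = np.asarray(window, dtype=float)
    if window.ndim != 2 or window.shape[0] != 6:
        raise ValueError(f"expected a 6xW window, got shape {window.shape}")
    if not np.all(np.isfinite(window)):
        raise ValueError("window contains non-finite values")
    power = _band_power(window, fs)
    if np.all(power < _SD_GUARD**2):
        logger.warning("all channels constant in window; defaulting to channel 0")
        return 0
    return int(np.argmax(power))


def zscore(values: np.ndarray) -> np.ndarray:
    """Per-epoch standardization; near-constant epochs map to all zeros."""
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("cannot z-score non-finite values")
    sd = values.std()
    if sd < _SD_GUARD:
        return np.zeros_like(values)
    return (values - values.mean()) / sd


def channel_correlation(values: np.ndarray) -> np.ndarray:
    """6x6 Pearson correlation matrix of a record or window.

    Constant channels get NaN rows/columns (flagged, never fabricated).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] != 6:
        raise ValueError("expected a 6xT array")
    if values.shape[1] < 2:
        raise ValueError("need at least 2 samples per channel")
    sd = values.std(axis=1)
    const = sd < _SD_GUARD
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = np.corrcoef(values)
    if const.any():
        logger.warning("constant channel(s) %s in correlation", np.flatnonzero(const))
        corr[const, :] = np.nan
        corr[:, const] = np.nan
        corr[const, const] = 1.0
    np.fill_diagonal(corr, 1.0)
    return corr


# --------------------------------------------------------------------------

def build_dataset(
    records,
    window_s: float = 10.0,
    overlap: float = 0.5,
    per_record_channel: bool = False,
) -> LabeledDataset:
    """Segment records, pick the strongest channel, and z-score each epoch.

    ``per_record_channel`` switches channel selection from per-window (the
    default) to a per-record majority vote.
    """
    epochs: list[Epoch] = []
    for rec in records:
        wins = segment(rec, window_s=window_s, overlap=overlap)
        if not wins:
            continue
        choices = [select_strongest_channel(w, rec.fs) for w, _, _ in wins]
        if per_record_channel:
            vote = int(np.bincount(choices).argmax())
            choices = [vote] * len(wins)
        for (win, label, widx), ch in zip(wins, choices):
            epochs.append(
                Epoch(
                    values=zscore(win[ch]),
                    label=label,
                    subject_id=rec.subject_id,
                    record_id=rec.record_id,
                    window_index=widx,
                    channel_index=ch,
                )
            )
    return LabeledDataset(epochs=epochs, split_assignment=["train"] * len(epochs))


def stratified_split(
    dataset: LabeledDataset,
    train_frac: float = 0.9,
    seed: int = 0,
    grouped: bool = False,
) -> LabeledDataset:
    """Proportional random train/validation split, per class.

    Per class, ``round(train_frac * n)`` epochs go to train and the rest to
    validation (at least one on each side). In grouped mode whole source
    records are assigned to one side, which removes overlap leakage between
    adjacent 50%-overlapping epochs at the cost of coarser proportions.
    """
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    counts = dataset.class_counts()
    for lab, n in counts.items():
        if 0 < n < 2:
            raise ValueError(f"class {lab!r} has {n} epoch(s); need >= 2 to split")
    rng = substream(seed, "split")
    assignment = np.array(["train"] * len(dataset.epochs), dtype=object)
    labels = np.array([e.label for e in dataset.epochs])
    if grouped:
        rec_ids = np.array([e.record_id for e in dataset.epochs])
        for lab in LABELS:
            recs = sorted(set(rec_ids[labels == lab]))
            if not recs:
                continue
            perm = rng.permutation(len(recs))
            n_val_target = max(1, int(round((1 - train_frac) * counts[lab])))
            val_recs, acc = [], 0
            for j in perm:
                if acc >= n_val_target:
                    break
                val_recs.append(recs[j])
                acc += int(np.sum(rec_ids == recs[j]))
            assignment[np.isin(rec_ids, val_recs)] = "val"
    else:
        for lab in LABELS:
            idx = np.flatnonzero(labels == lab)
            if idx.size == 0:
                continue
            n_train = int(round(train_frac * idx.size))
            n_train = min(max(n_train, 1), idx.size - 1)
            perm = rng.permutation(idx.size)
            assignment[idx[perm[n_train:]]] = "val"
    return LabeledDataset(
        epochs=dataset.epochs,
        split_assignment=assignment.tolist(),
        provenance={**dataset.provenance, "train_frac": train_frac,
                    "seed": int(seed), "grouped": bool(grouped)},
    )


def hold_out_records(
    dataset: LabeledDataset, record_ids, split_name: str = "test"
) -> LabeledDataset:
    """Move every epoch of the given source records into an isolated split."""
    record_ids = set(record_ids)
    assignment = list(dataset.split_assignment)
    for i, e in enumerate(dataset.epochs):
        if e.record_id in record_ids:
            assignment[i] = split_name
    return LabeledDataset(dataset.epochs, assignment, dict(dataset.provenance))


def epochs_table(dataset: LabeledDataset) -> pd.DataFrame:
    """Tabular epoch metadata (one row per epoch)."""
    return pd.DataFrame(
        {
            "record_id": [e.record_id for e in dataset.epochs],
            "subject_id": [e.subject_id for e in dataset.epochs],
            "window_index": [e.window_index for e in dataset.epochs],
            "channel_index": [e.channel_index for e in dataset.epochs],
            "label": [e.label for e in dataset.epochs],
            "split": list(dataset.split_assignment),
        }
    )


# --------------------------------------------------------------------------

_FEATURE_BANDS = ((0.05, 0.5), (0.5, 1.5), (1.5, 4.0), (4.0, 10.0))


def summary_features(values: np.ndarray, fs: float = 100.0) -> np.ndarray:
    """Hand-crafted per-epoch features: band powers, burst count, pause share.

    Used as a sanity floor: a linear classifier on these features must be
    able to separate the six simulated states.
    """
    x = np.asarray(values, dtype=float)
    total = _band_power(x[None, :], fs, (0.0, fs / 2))[0] + 1e-12
    bands = [
        _band_power(x[None, :], fs, b)[0] / total for b in _FEATURE_BANDS
    ]
    env = np.abs(x - x.mean())
    k = max(int(0.25 * fs), 1)
    env = np.convolve(env, np.ones(k) / k, mode="same")
    thresh = 2.0 * np.median(env)
    bursts = int(np.sum(np.diff((env > thresh).astype(int)) == 1))
    pause = float(np.mean(env < 0.1 * env.max())) if env.max() > 0 else 1.0
    # burstiness: kurtosis of the envelope (sparse grinding episodes are
    # heavy-tailed; cycle-locked snore bursts are not)
    ev = env - env.mean()
    m2 = np.mean(ev**2)
    kurt = float(np.mean(ev**4) / m2**2) if m2 > 0 else 3.0
    # breath periodicity: max autocorrelation at lags of 2-8 s
    xc = x - x.mean()
    denom = float(np.dot(xc, xc))
    if denom > 0:
        lags = np.arange(int(2 * fs), min(int(8 * fs), x.size - 1))
        ac = np.array([np.dot(xc[:-l], xc[l:]) / denom for l in lags[::10]])
        periodicity = float(ac.max()) if ac.size else 0.0
    else:
        periodicity = 0.0
    crest = float(env.max() / (np.sqrt(m2 + env.mean() ** 2) + 1e-12))
    return np.array(bands + [bursts, pause, kurt, periodicity, crest, float(np.var(x))])
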