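"""Record container for multichannel strain-sensor sessions.

A :class:`MultichannelRecord` holds the six-channel readout of one wearing
session of the garment: a ``6 x T`` signal matrix sampled at ``fs`` Hz,
interval annotations with one of the six sleep-state labels, and any
nocturnal-turning artifact events injected into (or observed in) the session.
Records are persisted as a per-record directory with a plain CSV signal table
(`signals.csv`: ``time_s, ch1..ch6``) and a JSON sidecar (`record.json`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

N_CHANNELS = 6

#: The six-state label vocabulary, in canonical (index) order.
LABELS = ("nasal", "mouth", "snore", "bruxism", "csa", "osa")
LABEL_TO_INDEX = {lab: i for i, lab in enumerate(LABELS)}

#: Signal-unit flags a record may declare.
UNITS = ("delta_r_over_r0", "current_a", "strain")


@dataclass
class ArtifactEvent:
    time_s: float
    magnitude: float
    isolated: bool

    def to_json(self) -> list:
        return [self.time_s, self.magnitude, bool(self.isolated)]


@dataclass
class MultichannelRecord:
    """One annotated six-channel session."""

    values: np.ndarray  # (6, T)
    fs: float
    annotations: list[tuple[float, float, str]] = field(default_factory=list)
    subject_id: str = "s0"
    record_id: str = "r0"
    unit: str = "delta_r_over_r0"
    artifact_events: list[ArtifactEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        if self.values.ndim != 2 or self.values.shape[0] != N_CHANNELS:
            raise ValueError(
                f"record must have exactly {N_CHANNELS} channel rows, "
                f"got shape {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("record contains non-finite values")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit flag {self.unit!r}")
        dur = self.duration_s
        prev_end = -np.inf
        for start, end, label in sorted(self.annotations):
            if label not in LABEL_TO_INDEX:
                raise ValueError(f"unknown label {label!r}; expected one of {LABELS}")
            if start < 0 or end < start or end > dur + 1e-9:
                raise ValueError(
                    f"annotation [{start}, {end}] outside record duration {dur:.3f} s"
                )
            if start < prev_end - 1e-9:
                raise ValueError("annotations overlap")
            prev_end = end

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def duration_s(self) -> float:
        return self.values.shape[1] / self.fs

    def copy(self) -> "MultichannelRecord":
        return MultichannelRecord(
            values=self.values.copy(),
            fs=self.fs,
            annotations=list(self.annotations),
            subject_id=self.subject_id,
            record_id=self.record_id,
            unit=self.unit,
            artifact_events=list(self.artifact_events),
        )


# -- on-disk format ---------------------------------------------------------

def write_record(record: MultichannelRecord, path: str | Path) -> Path:
    """Write one record directory (``signals.csv`` + ``record.json``)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    t = np.arange(record.n_samples) / record.fs
    frame = pd.DataFrame({"time_s": t})
    for i in range(N_CHANNELS):
        frame[f"ch{i + 1}"] = record.values[i]
    frame.to_csv(path / "signals.csv", index=False, float_format="%.9g")
    meta = {
        "fs": record.fs,
        "subject_id": record.subject_id,
        "record_id": record.record_id,
        "unit": record.unit,
        "annotations": [[s, e, lab] for s, e, lab in record.annotations],
        "artifact_events": [ev.to_json() for ev in record.artifact_events],
        "n_samples": record.n_samples,
    }
    (path / "record.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def read_record(path: str | Path) -> MultichannelRecord:
    """Read a record directory, validating schema and annotations."""
    path = Path(path)
    csv_path = path / "signals.csv"
    json_path = path / "record.json"
    if not csv_path.exists() or not json_path.exists():
        raise FileNotFoundError(f"{path} is not a record directory")
    frame = pd.read_csv(csv_path)
    expected = ["time_s"] + [f"ch{i + 1}" for i in range(N_CHANNELS)]
    missing = [c for c in expected if c not in frame.columns]
    if missing:
        raise ValueError(f"{csv_path}: missing column(s) {missing}")
    meta = json.loads(json_path.read_text())
    fs = float(meta["fs"])
    values = frame[[f"ch{i + 1}" for i in range(N_CHANNELS)]].to_numpy().T
    dur = values.shape[1] / fs
    for s, e, lab in meta.get("annotations", []):
        if e > dur + 1e-9:
            raise ValueError(
                f"{json_path}: annotation [{s}, {e}] ends after record duration {dur:.3f} s"
            )
    dt = np.diff(frame["time_s"].to_numpy())
    if len(dt) and not np.allclose(dt, 1.0 / fs, rtol=1e-6, atol=1e-9):
        raise ValueError(f"{csv_path}: time_s spacing inconsistent with fs={fs}")
    return MultichannelRecord(
        values=values,
        fs=fs,
        annotations=[(float(s), float(e), str(lab)) for s, e, lab in meta.get("annotations", [])],
        subject_id=str(meta.get("subject_id", "s0")),
        record_id=str(meta.get("record_id", path.name)),
        unit=str(meta.get("unit", "delta_r_over_r0")),
        artifact_events=[
            ArtifactEvent(float(t), float(m), bool(iso))
            for t, m, iso in meta.get("artifact_events", [])
        ],
    )
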