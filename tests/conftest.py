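"""Shared fixtures.

The heavy session fixtures (the full-scale default dataset and a model
trained on it) are built once and shared between the learnability,
transfer, explainability and embedding tests.
"""

import numpy as np
import pytest

import somnoweave as sw
from somnoweave.preprocessing import build_dataset, stratified_split
from somnoweave.simulate import SimConfig, perturb_for_subject, simulate_dataset
from somnoweave.sleepnet import SleepNetConfig, build_sleepnet
from somnoweave.training import TrainConfig, train

#: SleepNet scaled to tiny inputs, for fast mechanical tests.
TINY_NET = dict(
    input_len=100, proj_kernel=5, proj_stride=5, d_model=8, lstm_hidden=8,
    n_attn_blocks=1, n_heads=2, d_ff=16, dropout=0.0,
    resnet_channels=(8, 16), resnet_strides=(2, 1), resnet_kernel=3,
)


@pytest.fixture(scope="session")
def small_records():
    """Balanced 20-epochs-per-class simulated dataset, 2 subjects."""
    counts = {lab: 20 for lab in sw.LABELS}
    records, manifest = simulate_dataset(counts, SimConfig(), n_subjects=2, seed=7)
    return records, manifest


@pytest.fixture(scope="session")
def small_dataset(small_records):
    records, _ = small_records
    ds = build_dataset(records)
    return stratified_split(ds, train_frac=0.8, seed=3)


@pytest.fixture(scope="session")
def default_dataset():
    """The full-scale default dataset: reference per-class epoch counts."""
    records, manifest = simulate_dataset(
        sw.PAPER_CLASS_COUNTS, SimConfig(), n_subjects=5, seed=123
    )
    ds = build_dataset(records)
    ds = stratified_split(ds, train_frac=0.9, seed=5)
    ds.provenance["manifest"] = manifest
    return ds


@pytest.fixture(scope="session")
def trained_model(default_dataset):
    """SleepNet trained on the default dataset with pinned seeds."""
    model = build_sleepnet(SleepNetConfig(seed=42))
    cfg = TrainConfig(lr=3e-3, batch_size=64, max_epochs=12, patience=6, seed=99)
    model, history = train(model, default_dataset, cfg)
    return model, history


@pytest.fixture(scope="session")
def shifted_subject_dataset():
    """Epochs from one synthetic new wearer with domain shift (subject s90),
    absent from the default dataset's manifest."""
    base = SimConfig()
    shifted = perturb_for_subject(base, 90, seed=777)
    counts = {lab: 60 for lab in sw.LABELS}
    records, _ = simulate_dataset(counts, shifted, n_subjects=1, seed=901)
    for rec in records:
        rec.subject_id = "s90"
    for rec in records:
        rec.record_id = "s90-" + rec.record_id
    return build_dataset(records)
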