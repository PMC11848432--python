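"""Preprocessing contracts: segmentation arithmetic, channel selection,
normalization, correlation, and stratified splitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import somnoweave as sw
from somnoweave.preprocessing import (
    LabeledDataset,
    build_dataset,
    channel_correlation,
    hold_out_records,
    segment,
    select_strongest_channel,
    stratified_split,
    zscore,
)
from somnoweave.records import MultichannelRecord
from somnoweave.simulate import SimConfig, gen_source_waveform, project_to_array


def _record(duration_s, label="nasal", fs=100.0, rng=None):
    rng = rng or np.random.default_rng(0)
    n = int(duration_s * fs)
    values = rng.standard_normal((6, n))
    return MultichannelRecord(
        values=values, fs=fs, annotations=[(0.0, duration_s, label)]
    )


class TestSegment:
    def test_sixty_second_record_gives_eleven_windows(self):
        wins = segment(_record(60.0), window_s=10, overlap=0.5)
        assert len(wins) == 11

    def test_exactly_one_window_at_window_length(self):
        assert len(segment(_record(10.0))) == 1

    def test_no_window_below_window_length(self):
        assert len(segment(_record(9.9))) == 0

    def test_mixed_label_windows_dropped(self):
        rec = _record(30.0)
        rec.annotations = [(0.0, 14.0, "nasal"), (14.0, 30.0, "snore")]
        wins = segment(rec)
        # starts 0 (nasal), 15 and 20 (snore); starts 5 and 10 straddle
        labels = [lab for _, lab, _ in wins]
        assert labels == ["nasal", "snore", "snore"]

    def test_invalid_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            segment(_record(30.0), overlap=1.0)

    def test_non_integral_window_rejected(self):
        with pytest.raises(ValueError, match="integral"):
            segment(_record(30.0), window_s=0.105)

    @settings(max_examples=30, deadline=None)
    @given(
        duration=st.floats(min_value=10.0, max_value=300.0),
        overlap=st.sampled_from([0.0, 0.5, 0.8]),
    )
    def test_count_formula_matches_enumeration(self, duration, overlap):
        """floor((T - W)/S) + 1 against brute-force window-start listing."""
        fs = 10.0
        n = int(duration * fs)
        rec = MultichannelRecord(
            values=np.zeros((6, n)) + np.arange(n),
            fs=fs,
            annotations=[(0.0, n / fs, "nasal")],
        )
        w = int(10 * fs)
        s = int(round(10 * (1 - overlap) * fs))
        brute = [i for i in range(0, n, s) if i + w <= n]
        wins = segment(rec, window_s=10, overlap=overlap)
        assert len(wins) == len(brute)
        assert len(wins) == int(np.floor((n - w) / s)) + 1


class TestChannelSelection:
    def test_scaled_channel_wins(self):
        rng = np.random.default_rng(1)
        base = np.sin(2 * np.pi * 0.3 * np.arange(1000) / 100.0)
        win = np.stack([base + 0.01 * rng.standard_normal(1000) for _ in range(6)])
        win[2] = 3 * base
        assert select_strongest_channel(win) == 2

    def test_identical_channels_tie_break_to_zero(self):
        base = np.sin(2 * np.pi * 0.3 * np.arange(1000) / 100.0)
        win = np.tile(base, (6, 1))
        assert select_strongest_channel(win) == 0

    def test_constant_input_returns_zero_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            idx = select_strongest_channel(np.ones((6, 500)))
        assert idx == 0
        assert any("constant" in r.message for r in caplog.records)

    def test_simulated_gain_dominant_channel_selected(self):
        cfg = SimConfig(channel_gains=(1.0, 1.0, 2.0, 1.0, 1.0, 1.0))
        x = gen_source_waveform("nasal", cfg, 120, np.random.default_rng(2))
        rec = project_to_array(x, cfg, np.random.default_rng(3), label="nasal")
        wins = segment(rec)
        hits = sum(select_strongest_channel(w) == 2 for w, _, _ in wins)
        assert hits / len(wins) >= 0.99


class TestZscore:
    def test_constant_vector_guard(self):
        assert np.all(zscore(np.full(100, 3.7)) == 0)

    def test_mean_zero_sd_one(self):
        x = np.random.default_rng(0).standard_normal(500) * 7 + 3
        z = zscore(x)
        assert abs(z.mean()) < 1e-6 and abs(z.std() - 1) < 1e-6

    def test_affine_invariance(self):
        x = np.random.default_rng(1).standard_normal(200)
        np.testing.assert_allclose(zscore(x), zscore(5 * x + 3), atol=1e-9)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            zscore(np.array([1.0, np.nan]))


class TestChannelCorrelation:
    def test_identical_channels_all_ones(self):
        x = np.tile(np.random.default_rng(0).standard_normal(100), (6, 1))
        np.testing.assert_allclose(channel_correlation(x), np.ones((6, 6)), atol=1e-12)

    def test_negated_channel_gives_minus_one(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((6, 200))
        x[3] = -x[0]
        corr = channel_correlation(x)
        assert corr[0, 3] == pytest.approx(-1.0)

    def test_symmetric_unit_diagonal_bounded(self):
        x = np.random.default_rng(2).standard_normal((6, 300))
        corr = channel_correlation(x)
        np.testing.assert_allclose(corr, corr.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(corr), 1.0)
        assert np.all(corr >= -1 - 1e-12) and np.all(corr <= 1 + 1e-12)

    def test_constant_channel_marked_undefined(self, caplog):
        x = np.random.default_rng(3).standard_normal((6, 100))
        x[4] = 2.0
        with caplog.at_level("WARNING"):
            corr = channel_correlation(x)
        assert np.isnan(corr[4, 0]) and np.isnan(corr[0, 4])
        assert corr[4, 4] == 1.0


class TestStratifiedSplit:
    def _dataset(self, counts):
        rng = np.random.default_rng(0)
        epochs = []
        from somnoweave.preprocessing import Epoch

        for lab, n in counts.items():
            for i in range(n):
                epochs.append(
                    Epoch(
                        values=rng.standard_normal(100),
                        label=lab,
                        subject_id="s0",
                        record_id=f"{lab}-r{i // 5}",
                        window_index=i,
                        channel_index=0,
                    )
                )
        return LabeledDataset(epochs, ["train"] * len(epochs))

    def test_ninety_ten_split_arithmetic(self):
        ds = stratified_split(self._dataset({"nasal": 10, "mouth": 10}), 0.9, seed=0)
        assert ds.class_counts("train") == {
            "nasal": 9, "mouth": 9, "snore": 0, "bruxism": 0, "csa": 0, "osa": 0
        }
        assert ds.class_counts("val")["nasal"] == 1

    def test_per_class_rounding_on_reference_counts(self):
        ds = stratified_split(self._dataset(sw.PAPER_CLASS_COUNTS), 0.9, seed=1)
        expected_train = sum(
            int(round(0.9 * n)) for n in sw.PAPER_CLASS_COUNTS.values()
        )
        assert ds.indices("train").size == expected_train
        assert ds.indices("train").size + ds.indices("val").size == 2119

    def test_same_seed_same_assignment(self):
        base = self._dataset({"nasal": 20, "csa": 8})
        a = stratified_split(base, 0.8, seed=5)
        b = stratified_split(base, 0.8, seed=5)
        assert a.split_assignment == b.split_assignment

    def test_small_class_rejected(self):
        with pytest.raises(ValueError, match="need >= 2"):
            stratified_split(self._dataset({"nasal": 5, "csa": 1}), 0.9, seed=0)

    def test_grouped_split_keeps_records_whole(self):
        ds = stratified_split(
            self._dataset({"nasal": 40, "mouth": 40}), 0.8, seed=2, grouped=True
        )
        for split in ("train", "val"):
            recs = {ds.epochs[i].record_id for i in ds.indices(split)}
            other = {ds.epochs[i].record_id
                     for i in ds.indices("val" if split == "train" else "train")}
            assert recs.isdisjoint(other)

    def test_isolated_test_records_disjoint(self, small_dataset):
        rec_ids = sorted({e.record_id for e in small_dataset.epochs})[:2]
        ds = hold_out_records(small_dataset, rec_ids)
        test_recs = {ds.epochs[i].record_id for i in ds.indices("test")}
        assert test_recs == set(rec_ids)
        for split in ("train", "val"):
            assert all(
                ds.epochs[i].record_id not in test_recs for i in ds.indices(split)
            )


class TestBuildDataset:
    def test_epochs_are_normalized(self, small_dataset):
        for e in small_dataset.epochs[:20]:
            assert len(e.values) == 1000
            assert abs(e.values.mean()) < 1e-6
            assert abs(e.values.std() - 1) < 1e-6 or np.all(e.values == 0)

    def test_pipeline_deterministic(self, small_records):
        records, _ = small_records
        a = build_dataset(records)
        b = build_dataset(records)
        for ea, eb in zip(a.epochs, b.epochs):
            np.testing.assert_array_equal(ea.values, eb.values)
            assert ea.channel_index == eb.channel_index
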