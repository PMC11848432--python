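"""Simulator contracts: spectral containment, channel correlation, pause and
burst structure, artifact behavior, dataset arithmetic, determinism."""

import dataclasses

import numpy as np
import pytest
from scipy.signal import periodogram

import somnoweave as sw
from somnoweave.preprocessing import channel_correlation, segment
from somnoweave.simulate import (
    SimConfig,
    gen_source_waveform,
    inject_turning,
    project_to_array,
    simulate_dataset,
    transduce,
)


def rms_envelope(x, fs=100.0, win_s=1.0):
    w = int(win_s * fs)
    return np.sqrt(np.convolve(x**2, np.ones(w) / w, mode="same"))


def spectral_fraction_below(x, fs, f_cut=10.0):
    f, p = periodogram(x - np.mean(x, axis=-1, keepdims=True), fs=fs, axis=-1)
    p = np.atleast_2d(p)
    return p[:, f < f_cut].sum() / p.sum()


class TestSourceWaveforms:
    def test_unknown_pattern_rejected(self):
        with pytest.raises(ValueError, match="unknown pattern"):
            gen_source_waveform("rem", SimConfig(), 60)

    def test_duration_below_one_breath_cycle_rejected(self):
        with pytest.raises(ValueError, match="breath cycle"):
            gen_source_waveform("nasal", SimConfig(breath_rate_hz=0.2), 3.0)

    def test_zero_amplitude_gives_zero_waveform(self):
        cfg = SimConfig(breath_amplitude=0.0)
        for pat in sw.LABELS:
            x = gen_source_waveform(pat, cfg, 30, np.random.default_rng(0))
            assert np.all(x == 0)

    def test_nasal_fft_peak_at_breath_rate(self):
        cfg = SimConfig(breath_rate_hz=0.25)
        x = gen_source_waveform("nasal", cfg, 60, np.random.default_rng(4))
        spec = np.abs(np.fft.rfft(x - x.mean()))
        freqs = np.fft.rfftfreq(x.size, 1 / cfg.fs)
        assert abs(freqs[spec.argmax()] - 0.25) <= 0.02

    @pytest.mark.parametrize("pattern", sw.LABELS)
    @pytest.mark.parametrize("seed", [0, 1])
    def test_spectral_energy_below_10hz(self, pattern, seed):
        cfg = SimConfig()
        x = gen_source_waveform(pattern, cfg, 120, np.random.default_rng(seed))
        assert spectral_fraction_below(x, cfg.fs) >= 0.95

    def test_csa_silent_fraction_matches_pause_fraction(self):
        cfg = SimConfig(csa_pause_fraction=0.4)
        x = gen_source_waveform("csa", cfg, 120, np.random.default_rng(3))
        env = rms_envelope(x, cfg.fs)
        frac = float(np.mean(env < 0.05 * env.max()))
        assert 0.35 <= frac <= 0.45

    def test_bruxism_bursts_are_sparse_and_high_amplitude(self):
        cfg = SimConfig()
        x, info = gen_source_waveform(
            "bruxism", cfg, 120, np.random.default_rng(5), with_info=True
        )
        assert len(info["events"]) > 0
        env = rms_envelope(x, cfg.fs, 0.5)
        mask = np.zeros(x.size, dtype=bool)
        for a, b in info["events"]:
            mask[int(a * cfg.fs): int(b * cfg.fs)] = True
        assert env[mask].mean() > 2.0 * env[~mask].mean()

    def test_mouth_and_nasal_differ_in_harmonic_content(self):
        cfg = SimConfig()
        rng = np.random.default_rng(6)
        xn = gen_source_waveform("nasal", cfg, 120, rng)
        xm = gen_source_waveform("mouth", cfg, 120, np.random.default_rng(6))

        def harmonic_share(x, f0):
            spec = np.abs(np.fft.rfft(x - x.mean())) ** 2
            freqs = np.fft.rfftfreq(x.size, 1 / cfg.fs)
            fund = spec[(freqs > 0.5 * f0) & (freqs < 1.5 * f0)].sum()
            upper = spec[(freqs >= 1.5 * f0) & (freqs < 10)].sum()
            return upper / (fund + upper)

        assert harmonic_share(xm, cfg.breath_rate_hz * cfg.mouth_rate_scale) > \
            harmonic_share(xn, cfg.breath_rate_hz)


class TestTransduce:
    def test_gauge_relation(self):
        cfg = SimConfig(gauge_factor=100.0)
        out = transduce(np.array([0.01]), cfg)
        assert out["dr_r0"][0] == pytest.approx(1.0)

    def test_ohms_law_baseline(self):
        cfg = SimConfig(gauge_factor=100.0, baseline_resistance_ohm=1e4, readout_voltage_v=1.0)
        out = transduce(np.array([0.0]), cfg)
        assert out["current_a"][0] == pytest.approx(1e-4)

    def test_current_monotone_decreasing_in_strain(self):
        cfg = SimConfig(gauge_factor=100.0, baseline_resistance_ohm=1e4, readout_voltage_v=1.0)
        ramp = np.linspace(0, 0.01, 101)
        current = transduce(ramp, cfg)["current_a"]
        # pointwise Ohm's-law oracle
        np.testing.assert_allclose(current, 1.0 / (1e4 * (1 + 100 * ramp)))
        assert current[0] == pytest.approx(1e-4)
        assert current[-1] == pytest.approx(5e-5)
        assert np.all(np.diff(current) < 0)

    def test_out_of_range_strain_rejected(self):
        with pytest.raises(ValueError, match="out of sensor range"):
            transduce(np.array([-0.02]), SimConfig(gauge_factor=100.0))


class TestArrayProjection:
    def test_zero_noise_gives_perfect_correlation(self):
        cfg = SimConfig(channel_noise_sd=0.0)
        x = gen_source_waveform("nasal", cfg, 30, np.random.default_rng(0))
        rec = project_to_array(x, cfg, np.random.default_rng(1))
        corr = channel_correlation(rec.values)
        assert corr.min() == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("pattern", sw.LABELS)
    def test_default_noise_keeps_channels_strongly_correlated(self, pattern):
        cfg = SimConfig()
        x = gen_source_waveform(pattern, cfg, 60, np.random.default_rng(2))
        rec = project_to_array(x, cfg, np.random.default_rng(3))
        corr = channel_correlation(rec.values)
        off = corr[~np.eye(6, dtype=bool)]
        assert off.min() > 0.9

    def test_strongest_power_channel_matches_largest_gain(self):
        cfg = SimConfig(channel_gains=(3.0, 1.0, 1.0, 1.0, 1.0, 1.0))
        x = gen_source_waveform("nasal", cfg, 30, np.random.default_rng(4))
        rec = project_to_array(x, cfg, np.random.default_rng(5))
        powers = (rec.values - rec.values.mean(axis=1, keepdims=True)).var(axis=1)
        assert powers.argmax() == 0

    def test_correlation_decreases_with_noise(self):
        x = gen_source_waveform("nasal", SimConfig(), 60, np.random.default_rng(6))
        mins = []
        for sd in (0.0, 0.05, 0.2, 0.8):
            cfg = SimConfig(channel_noise_sd=sd)
            rec = project_to_array(x, cfg, np.random.default_rng(7))
            corr = channel_correlation(rec.values)
            mins.append(corr[~np.eye(6, dtype=bool)].min())
        assert all(a > b for a, b in zip(mins, mins[1:]))


class TestTurningArtifacts:
    def _clean_record(self):
        cfg = SimConfig(breath_amplitude=0.0, channel_noise_sd=0.0)
        x = np.zeros(int(120 * cfg.fs))
        return cfg, project_to_array(x, cfg, np.random.default_rng(0))

    def test_zero_magnitude_is_identity(self):
        cfg, rec = self._clean_record()
        out = inject_turning(rec, (60.0, 0.0), isolated=False, cfg=cfg)
        np.testing.assert_array_equal(out.values, rec.values)

    def test_event_outside_record_rejected(self):
        cfg, rec = self._clean_record()
        with pytest.raises(ValueError, match="outside record"):
            inject_turning(rec, (500.0, 1.0), isolated=False, cfg=cfg)

    def test_isolation_attenuates_peak_amplitude(self):
        cfg, rec = self._clean_record()
        raw = inject_turning(rec, (30.0, 2.0), isolated=False, cfg=cfg)
        iso = inject_turning(rec, (30.0, 2.0), isolated=True, cfg=cfg)
        peak_raw = np.abs(raw.values - rec.values).max()
        peak_iso = np.abs(iso.values - rec.values).max()
        assert peak_iso / peak_raw == pytest.approx(
            cfg.artifact_amplitude_attenuation, rel=1e-3
        )

    def test_drift_shifts_post_event_baseline(self):
        cfg, rec = self._clean_record()
        out = inject_turning(rec, (30.0, 2.0), isolated=False, cfg=cfg)
        fs = int(cfg.fs)
        pre = out.values[:, : 25 * fs].mean()
        post = out.values[:, 60 * fs:].mean()  # >= 30 s after the event
        assert post - pre == pytest.approx(2.0 * cfg.artifact_drift_fraction, rel=0.02)

    def test_isolation_attenuates_drift(self):
        cfg, rec = self._clean_record()
        raw = inject_turning(rec, (30.0, 2.0), isolated=False, cfg=cfg)
        iso = inject_turning(rec, (30.0, 2.0), isolated=True, cfg=cfg)
        fs = int(cfg.fs)
        drift_raw = raw.values[:, 60 * fs:].mean()
        drift_iso = iso.values[:, 60 * fs:].mean()
        assert drift_iso / drift_raw == pytest.approx(
            cfg.artifact_drift_attenuation, rel=0.05
        )

    def test_event_recorded(self):
        cfg, rec = self._clean_record()
        out = inject_turning(rec, (30.0, 1.5), isolated=True, cfg=cfg)
        assert len(out.artifact_events) == 1
        assert out.artifact_events[0].isolated is True
        assert rec.artifact_events == []


class TestSimulateDataset:
    def test_reference_counts_yield_reference_total(self):
        total = sum(sw.PAPER_CLASS_COUNTS.values())
        assert total == 2119

    def test_empty_counts_give_empty_manifest(self):
        records, manifest = simulate_dataset({}, SimConfig(), n_subjects=1, seed=0)
        assert records == [] and manifest["records"] == []

    def test_single_class_counts_exact_after_segmentation(self):
        records, _ = simulate_dataset({"nasal": 10}, SimConfig(), n_subjects=1, seed=0)
        n_epochs = sum(len(segment(r)) for r in records)
        assert n_epochs == 10
        assert all(lab == "nasal" for r in records for _, _, lab in
                   [(None, None, a[2]) for a in r.annotations])

    def test_requested_counts_exact_after_segmentation(self, small_records):
        records, manifest = small_records
        got = {lab: 0 for lab in sw.LABELS}
        for rec in records:
            for _, lab, _ in segment(rec):
                got[lab] += 1
        assert got == manifest["class_totals"]

    def test_infeasible_duration_rejected(self):
        cfg = SimConfig(max_record_duration_s=5.0)
        with pytest.raises(ValueError, match="feasible maximum"):
            simulate_dataset({"nasal": 5}, cfg, n_subjects=1, seed=0)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError, match="negative count"):
            simulate_dataset({"nasal": -1}, SimConfig(), n_subjects=1, seed=0)

    def test_determinism_bit_identical(self):
        counts = {"nasal": 4, "csa": 3}
        rec1, man1 = simulate_dataset(counts, SimConfig(), n_subjects=2, seed=11)
        rec2, man2 = simulate_dataset(counts, SimConfig(), n_subjects=2, seed=11)
        assert man1 == man2
        for a, b in zip(rec1, rec2):
            np.testing.assert_array_equal(a.values, b.values)

    def test_subject_perturbations_differ(self):
        records, _ = simulate_dataset({"nasal": 8}, SimConfig(), n_subjects=2, seed=3)
        by_subject = {}
        for r in records:
            by_subject.setdefault(r.subject_id, []).append(r)
        assert len(by_subject) == 2


def test_simconfig_validation():
    with pytest.raises(ValueError, match="6 channel gains"):
        SimConfig(channel_gains=(1.0, 1.0))
    with pytest.raises(ValueError, match="Nyquist"):
        SimConfig(fs=10.0)
    with pytest.raises(ValueError, match=">= 0"):
        SimConfig(channel_noise_sd=-0.1)
    # dataclass replace keeps validation
    cfg = SimConfig()
    with pytest.raises(ValueError):
        dataclasses.replace(cfg, csa_pause_fraction=1.5)
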