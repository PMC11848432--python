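"""Synthetic six-channel laryngeal strain-signal simulator.

Generates labeled sessions that mimic the statistical structure of
collar-mounted strain-sensor recordings of sleep activity: six sleep states
(nasal breath, mouth breath, snoring, bruxism, central and obstructive sleep
apnea), all spectral energy in the sub-10 Hz band, six strongly correlated
channels that differ only by gain and independent noise, and optional
nocturnal-turning artifacts whose severity depends on a strain-isolation
flag.

The waveform kernels are parametric sketches of the qualitative phenomenology
of each state (quasi-periodic breath carriers, inspiration-locked snore
bursts, sparse high-amplitude grinding bursts, apneic pauses, obstructed
effort oscillations); they are a test fixture for the recognition pipeline,
not a physiological model.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from ._seeding import child_seed, substream
from .records import LABELS, ArtifactEvent, MultichannelRecord

__all__ = [
    "SimConfig",
    "PAPER_CLASS_COUNTS",
    "gen_source_waveform",
    "transduce",
    "project_to_array",
    "inject_turning",
    "simulate_dataset",
    "perturb_for_subject",
]

#: Usable epoch counts per class reported for the reference dataset.
PAPER_CLASS_COUNTS = {
    "nasal": 728,
    "mouth": 701,
    "snore": 262,
    "bruxism": 180,
    "csa": 102,
    "osa": 146,
}


@dataclass
class SimConfig:
    """All knobs of the signal simulator.

    Amplitudes are in strain units (dimensionless elongation); the readout
    stage converts strain to relative resistance change via the gauge factor.
    Every spectral component of every generator sits below 10 Hz, the band
    that carries laryngeal vibration information.
    """

    fs: float = 100.0
    duration_s: float = 60.0

    # breath carrier
    breath_rate_hz: float = 0.25          # resting range roughly 0.15-0.4 Hz
    breath_amplitude: float = 0.005       # ~0.5 % strain
    nasal_harmonics: tuple = (1.0, 0.25, 0.08)
    mouth_harmonics: tuple = (1.0, 0.5, 0.22, 0.1)
    nasal_asymmetry: float = 0.1          # inhale/exhale waveform skew
    mouth_asymmetry: float = 0.5
    mouth_rate_scale: float = 0.85        # mouth breathing slightly slower

    # snoring: inspiration-locked burst oscillation
    snore_burst_band_hz: tuple = (4.0, 9.0)
    snore_burst_gain: float = 1.6

    # bruxism: sparse grinding bursts over a faint carrier
    bruxism_event_rate_per_min: float = 10.0
    bruxism_burst_gain: float = 3.0
    bruxism_burst_duration_s: float = 0.8
    bruxism_carrier_scale: float = 0.5
    bruxism_osc_hz: float = 7.0

    # central sleep apnea: silent respiratory pauses, dense enough that
    # every 10-s epoch of a CSA session overlaps at least one pause
    csa_pause_s: float = 8.0
    csa_pause_fraction: float = 0.5
    csa_ramp_s: float = 0.3

    # obstructive sleep apnea: obstructed effort vs recovery breathing
    osa_effort_gain: float = 1.3
    osa_effort_band_hz: tuple = (0.8, 3.0)
    osa_obstruction_duty: float = 0.7
    osa_cycle_s: float = 20.0
    osa_obstructed_carrier_scale: float = 0.3
    osa_recovery_scale: float = 1.6

    # transduction (strain -> resistance -> current readout)
    gauge_factor: float = 100.0
    baseline_resistance_ohm: float = 10_000.0
    readout_voltage_v: float = 1.0

    # array projection
    channel_gains: tuple = (1.0, 0.85, 1.15, 0.95, 1.05, 0.9)
    channel_noise_sd: float = 0.04        # in dR/R0 units

    # nocturnal-turning artifacts
    turning_events: tuple = ()            # list of (time_s, magnitude)
    strain_isolation: bool = False
    artifact_amplitude_attenuation: float = 0.2
    artifact_drift_attenuation: float = 0.1
    artifact_drift_fraction: float = 0.3
    artifact_width_s: float = 1.5
    artifact_drift_tau_s: float = 5.0

    # dataset assembly
    max_record_duration_s: float = 600.0

    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.channel_gains) != 6:
            raise ValueError("exactly 6 channel gains are required")
        nonneg = {
            "breath_rate_hz": self.breath_rate_hz,
            "breath_amplitude": self.breath_amplitude,
            "snore_burst_gain": self.snore_burst_gain,
            "bruxism_event_rate_per_min": self.bruxism_event_rate_per_min,
            "bruxism_burst_gain": self.bruxism_burst_gain,
            "bruxism_burst_duration_s": self.bruxism_burst_duration_s,
            "csa_pause_s": self.csa_pause_s,
            "osa_effort_gain": self.osa_effort_gain,
            "channel_noise_sd": self.channel_noise_sd,
        }
        for name, v in nonneg.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if any(g < 0 for g in self.channel_gains):
            raise ValueError("channel gains must be >= 0")
        if not 0 <= self.csa_pause_fraction < 1:
            raise ValueError("csa_pause_fraction must be in [0, 1)")
        if not 0 < self.osa_obstruction_duty < 1:
            raise ValueError("osa_obstruction_duty must be in (0, 1)")
        nyq = self.fs / 2
        top = max(
            len(self.mouth_harmonics) * self.breath_rate_hz,
            self.snore_burst_band_hz[1],
            self.bruxism_osc_hz,
            self.osa_effort_band_hz[1],
        )
        if top >= nyq:
            raise ValueError(
                f"spectral component at {top} Hz exceeds Nyquist {nyq} Hz"
            )


# --------------------------------------------------------------------------
# waveform kernels
# --------------------------------------------------------------------------

def _time(duration_s: float, fs: float) -> np.ndarray:
    n = int(round(duration_s * fs))
    return np.arange(n) / fs


def _breath_carrier(
    t: np.ndarray,
    rate_hz: float,
    harmonics,
    asymmetry: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Quasi-periodic breath waveform with harmonic shaping and skew.

    Phase noise is a slow random walk (band-limited), so the fundamental
    stays a sharp spectral line while cycles vary slightly in length.
    """
    n = t.size
    fs = 1.0 / (t[1] - t[0]) if n > 1 else 1.0
    drift = rng.standard_normal(max(int(round(n * 0.05 / fs)) + 2, 4))
    drift = np.interp(np.linspace(0, 1, n), np.linspace(0, 1, drift.size), drift)
    phase = 2 * np.pi * rate_hz * t + 0.15 * drift
    # waveform skew: compresses one half-cycle, stretches the other
    phase = phase + asymmetry * np.sin(phase)
    x = np.zeros(n)
    for k, w in enumerate(harmonics, start=1):
        x += w * np.sin(k * phase)
    # slow amplitude modulation (breath-to-breath depth variation)
    am = 1.0 + 0.1 * np.sin(2 * np.pi * 0.02 * t + rng.uniform(0, 2 * np.pi))
    return x * am


def _bandnoise(n: int, fs: float, band, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to ``band`` (Hz)."""
    white = rng.standard_normal(n)
    lo, hi = band
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, white)
    sd = x.std()
    return x / sd if sd > 0 else x


def _inspiration_gate(phase_like: np.ndarray) -> np.ndarray:
    """Smooth 0..1 gate over the inspiratory half of each breath cycle."""
    return np.clip(phase_like, 0.0, None) ** 2


def gen_source_waveform(
    pattern: str,
    cfg: SimConfig,
    duration_s: float | None = None,
    rng: np.random.Generator | None = None,
    with_info: bool = False,
):
    """Generate one single-channel strain trace for a sleep state.

    Parameters
    ----------
    pattern:
        One of ``nasal, mouth, snore, bruxism, csa, osa``.
    duration_s:
        Trace length; must cover at least one breath cycle.
    with_info:
        Also return a dict of ground-truth event intervals (burst windows,
        apneic pauses, obstructed segments) for downstream validation.
    """
    if pattern not in LABELS:
        raise ValueError(f"unknown pattern {pattern!r}; expected one of {LABELS}")
    if duration_s is None:
        duration_s = cfg.duration_s
    rate = cfg.breath_rate_hz * (cfg.mouth_rate_scale if pattern == "mouth" else 1.0)
    if rate > 0 and duration_s < 1.0 / rate:
        raise ValueError(
            f"duration {duration_s} s shorter than one breath cycle ({1.0 / rate:.1f} s)"
        )
    if rng is None:
        rng = substream(cfg.seed, f"waveform/{pattern}")
    t = _time(duration_s, cfg.fs)
    n = t.size
    amp = cfg.breath_amplitude
    info: dict = {"events": []}

    if amp == 0:
        x = np.zeros(n)
        return (x, info) if with_info else x

    if pattern == "nasal":
        x = amp * _breath_carrier(t, rate, cfg.nasal_harmonics, cfg.nasal_asymmetry, rng)

    elif pattern == "mouth":
        x = 1.1 * amp * _breath_carrier(t, rate, cfg.mouth_harmonics, cfg.mouth_asymmetry, rng)

    elif pattern == "snore":
        carrier = _breath_carrier(t, rate, cfg.nasal_harmonics, 0.2, rng)
        gate = _inspiration_gate(carrier)
        gate /= max(gate.max(), 1e-12)
        burst = _bandnoise(n, cfg.fs, cfg.snore_burst_band_hz, rng)
        # per-cycle loudness variation makes snoring irregular
        slow = 1.0 + 0.5 * _bandnoise(n, cfg.fs, (0.05, 0.2), rng).clip(-1.5, 1.5)
        x = amp * (carrier + cfg.snore_burst_gain * gate * burst * np.abs(slow))
        info["events"] = _mask_to_intervals(gate > 0.3, cfg.fs)

    elif pattern == "bruxism":
        carrier = cfg.bruxism_carrier_scale * _breath_carrier(
            t, rate, cfg.nasal_harmonics, cfg.nasal_asymmetry, rng
        )
        x = amp * carrier
        n_events = rng.poisson(cfg.bruxism_event_rate_per_min * duration_s / 60.0)
        events = []
        for _ in range(n_events):
            dur = max(0.2, rng.normal(cfg.bruxism_burst_duration_s, 0.2))
            start = rng.uniform(0, max(duration_s - dur, 1e-3))
            i0, i1 = int(start * cfg.fs), min(int((start + dur) * cfg.fs), n)
            if i1 <= i0:
                continue
            w = np.hanning(i1 - i0)
            osc = np.sin(2 * np.pi * cfg.bruxism_osc_hz * t[i0:i1] + rng.uniform(0, 2 * np.pi))
            rough = 0.5 * _bandnoise(i1 - i0, cfg.fs, (5.0, 9.0), rng) if i1 - i0 > 30 else 0.0
            x[i0:i1] += amp * cfg.bruxism_burst_gain * w * (osc + rough)
            events.append((start, start + dur))
        info["events"] = events

    elif pattern == "csa":
        carrier = _breath_carrier(t, rate, cfg.nasal_harmonics, cfg.nasal_asymmetry, rng)
        env = np.ones(n)
        pauses = _schedule_pauses(
            duration_s, cfg.csa_pause_s, cfg.csa_pause_fraction, rng
        )
        ramp = max(int(cfg.csa_ramp_s * cfg.fs), 1)
        for p0, p1 in pauses:
            i0, i1 = int(p0 * cfg.fs), min(int(p1 * cfg.fs), n)
            if i1 <= i0:
                continue
            env[i0:i1] = 0.02  # residual cardiac/muscle microvibration
            # smooth on/off ramps placed outside the nominal pause span
            r0 = min(ramp, i0)
            if r0 > 0:
                env[i0 - r0: i0] = np.linspace(1, 0.02, r0)
            r1 = min(ramp, n - i1)
            if r1 > 0:
                env[i1: i1 + r1] = np.linspace(0.02, 1, r1)
        x = amp * carrier * env
        info["events"] = pauses

    elif pattern == "osa":
        carrier = _breath_carrier(t, rate, cfg.nasal_harmonics, cfg.nasal_asymmetry, rng)
        effort = _bandnoise(n, cfg.fs, cfg.osa_effort_band_hz, rng)
        am = np.abs(1.0 + 0.6 * _bandnoise(n, cfg.fs, (0.05, 0.3), rng))
        obstructed = np.zeros(n, dtype=bool)
        cyc = cfg.osa_cycle_s
        tt = 0.0
        segs = []
        while tt < duration_s:
            o1 = min(tt + cfg.osa_obstruction_duty * cyc, duration_s)
            obstructed[int(tt * cfg.fs): int(o1 * cfg.fs)] = True
            segs.append((tt, o1))
            tt += cyc
        x = np.where(
            obstructed,
            amp * (cfg.osa_obstructed_carrier_scale * carrier
                   + cfg.osa_effort_gain * effort * am),
            amp * cfg.osa_recovery_scale * carrier,
        )
        info["events"] = segs

    return (x, info) if with_info else x


def _schedule_pauses(duration_s, pause_s, fraction, rng):
    """Place non-overlapping apneic pauses covering ~``fraction`` of the trace."""
    if fraction <= 0 or pause_s <= 0:
        return []
    n_pauses = int(round(fraction * duration_s / pause_s))
    if n_pauses == 0:
        return []
    # evenly spaced slots with jittered starts, always leaving breathing gaps
    slot = duration_s / n_pauses
    pauses = []
    for i in range(n_pauses):
        gap = slot - pause_s
        start = i * slot + rng.uniform(0.1, max(gap - 0.1, 0.11)) if gap > 0.3 else i * slot
        pauses.append((start, min(start + pause_s, duration_s)))
    return pauses


def _mask_to_intervals(mask: np.ndarray, fs: float):
    edges = np.flatnonzero(np.diff(mask.astype(int)))
    idx = np.concatenate([[0], edges + 1, [mask.size]])
    out = []
    for a, b in zip(idx[:-1], idx[1:]):
        if mask[a]:
            out.append((a / fs, b / fs))
    return out


# --------------------------------------------------------------------------
# transduction and array projection
# --------------------------------------------------------------------------

def transduce(strain: np.ndarray, cfg: SimConfig) -> dict:
    """Convert a strain trace to sensor readout.

    The piezoresistive relation is dR/R0 = GF * strain; with a constant
    supply voltage V across the sensor the measured current is
    I = V / (R0 * (1 + dR/R0)), monotone decreasing in strain.
    """
    if cfg.gauge_factor <= 0 or cfg.baseline_resistance_ohm <= 0:
        raise ValueError("gauge_factor and baseline_resistance_ohm must be positive")
    strain = np.asarray(strain, dtype=float)
    dr_r0 = cfg.gauge_factor * strain
    if np.any(1.0 + dr_r0 <= 0):
        raise ValueError("strain drives resistance non-positive; out of sensor range")
    current = cfg.readout_voltage_v / (cfg.baseline_resistance_ohm * (1.0 + dr_r0))
    return {"dr_r0": dr_r0, "current_a": current}


def project_to_array(
    source: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    label: str | None = None,
    subject_id: str = "s0",
    record_id: str = "r0",
) -> MultichannelRecord:
    """Project one source strain trace onto the six-channel array.

    Each channel sees the same vibration scaled by its positional gain plus
    independent sensor noise, which reproduces the strongly correlated
    multichannel structure of the garment (the crossbar circuit is reduced
    to a per-channel scalar gain). Output unit is dR/R0.
    """
    if rng is None:
        rng = substream(cfg.seed, f"array/{record_id}")
    source = np.asarray(source, dtype=float)
    n = source.size
    values = np.empty((6, n))
    for i, g in enumerate(cfg.channel_gains):
        dr = cfg.gauge_factor * g * source  # piezoresistive gauge relation
        values[i] = dr + rng.normal(0.0, cfg.channel_noise_sd, size=n)
    annotations = []
    if label is not None:
        annotations = [(0.0, n / cfg.fs, label)]
    return MultichannelRecord(
        values=values,
        fs=cfg.fs,
        annotations=annotations,
        subject_id=subject_id,
        record_id=record_id,
        unit="delta_r_over_r0",
    )


def inject_turning(
    record: MultichannelRecord,
    event: tuple,
    isolated: bool | None = None,
    cfg: SimConfig | None = None,
) -> MultichannelRecord:
    """Add a nocturnal-turning artifact (pulse + baseline drift) to a record.

    With strain isolation the garment's rigid surround redistributes motion
    strain away from the sensing area: peak artifact amplitude is attenuated
    by ``artifact_amplitude_attenuation`` and the residual drift by
    ``artifact_drift_attenuation`` relative to the untreated garment.
    """
    cfg = cfg or SimConfig()
    if isolated is None:
        isolated = cfg.strain_isolation
    time_s, magnitude = float(event[0]), float(event[1])
    if magnitude < 0:
        raise ValueError("artifact magnitude must be >= 0")
    if not 0 <= time_s <= record.duration_s:
        raise ValueError(
            f"turning event at {time_s} s outside record of {record.duration_s:.1f} s"
        )
    out = record.copy()
    if magnitude == 0:
        return out
    amp = magnitude * (cfg.artifact_amplitude_attenuation if isolated else 1.0)
    drift_level = magnitude * cfg.artifact_drift_fraction * (
        cfg.artifact_drift_attenuation if isolated else 1.0
    )
    t = np.arange(record.n_samples) / record.fs
    sigma = cfg.artifact_width_s / 4.0
    pulse = amp * np.exp(-0.5 * ((t - time_s) / sigma) ** 2)
    after = t >= time_s
    drift = np.zeros_like(t)
    drift[after] = drift_level * (1.0 - np.exp(-(t[after] - time_s) / cfg.artifact_drift_tau_s))
    out.values = out.values + pulse + drift
    out.artifact_events = list(out.artifact_events) + [
        ArtifactEvent(time_s, magnitude, bool(isolated))
    ]
    return out


# --------------------------------------------------------------------------
# dataset assembly
# --------------------------------------------------------------------------

def perturb_for_subject(cfg: SimConfig, subject_index: int, seed: int) -> SimConfig:
    """Per-subject domain shift: gain, breath-rate, and noise jitter.

    New wearers differ in collar fit and anatomy; this is emulated as
    multiplicative jitter of channel gains (+-20%), breathing rate (+-15%),
    and sensor noise (+-30%), all seeded.
    """
    rng = substream(seed, f"subject/{subject_index}")
    gains = tuple(
        float(g * rng.uniform(0.8, 1.2)) for g in cfg.channel_gains
    )
    return replace(
        cfg,
        channel_gains=gains,
        breath_rate_hz=cfg.breath_rate_hz * rng.uniform(0.85, 1.15),
        channel_noise_sd=cfg.channel_noise_sd * rng.uniform(0.7, 1.3),
        seed=child_seed(seed, f"subject-cfg/{subject_index}"),
    )


def _epochs_to_duration(n_epochs: int, window_s: float, hop_s: float) -> float:
    return window_s + hop_s * (n_epochs - 1)


def simulate_dataset(
    class_counts: dict,
    cfg: SimConfig | None = None,
    n_subjects: int = 5,
    seed: int = 0,
    window_s: float = 10.0,
    overlap: float = 0.5,
):
    """Simulate a full labeled dataset with exact downstream epoch counts.

    Record durations are chosen so that segmentation with the given window
    and overlap yields exactly ``class_counts[label]`` usable epochs per
    class. Counts are spread across ``n_subjects`` wearers, each with its own
    seeded domain-shift perturbation.

    Returns ``(records, manifest)``.
    """
    cfg = cfg or SimConfig()
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    hop_s = window_s * (1.0 - overlap)
    max_per_record = int(np.floor((cfg.max_record_duration_s - window_s) / hop_s)) + 1
    if max_per_record < 1:
        raise ValueError(
            "max_record_duration_s too short for a single epoch; feasible maximum: 0 epochs"
        )
    for label, count in class_counts.items():
        if label not in LABELS:
            raise ValueError(f"unknown class label {label!r}")
        if count < 0:
            raise ValueError(f"negative count for {label}")

    records: list[MultichannelRecord] = []
    entries = []
    subject_cfgs = [perturb_for_subject(cfg, i, seed) for i in range(n_subjects)]
    for label in LABELS:
        total = int(class_counts.get(label, 0))
        if total == 0:
            continue
        base, rem = divmod(total, n_subjects)
        for subj in range(n_subjects):
            n_sub = base + (1 if subj < rem else 0)
            chunk_idx = 0
            while n_sub > 0:
                n_rec = min(n_sub, max_per_record)
                n_sub -= n_rec
                dur = _epochs_to_duration(n_rec, window_s, hop_s)
                rid = f"{label}-s{subj}-c{chunk_idx}"
                rng = substream(seed, f"record/{rid}")
                scfg = subject_cfgs[subj]
                wav = gen_source_waveform(label, scfg, duration_s=dur, rng=rng)
                rec = project_to_array(
                    wav, scfg, rng=rng, label=label,
                    subject_id=f"s{subj}", record_id=rid,
                )
                records.append(rec)
                entries.append(
                    {
                        "record_id": rid,
                        "subject_id": f"s{subj}",
                        "label": label,
                        "duration_s": dur,
                        "n_epochs": n_rec,
                    }
                )
                chunk_idx += 1

    manifest = {
        "seed": int(seed),
        "n_subjects": int(n_subjects),
        "window_s": window_s,
        "overlap": overlap,
        "class_totals": {lab: int(class_counts.get(lab, 0)) for lab in LABELS},
        "records": entries,
        "subjects": sorted({e["subject_id"] for e in entries}),
        "sim_config": dataclasses.asdict(cfg),
    }
    return records, manifest
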