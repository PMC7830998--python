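"""Synthetic EGG study sessions with known ground truth.

The generator emulates a three-trial driving-simulator protocol: a 15-min
baseline, a 15-min simulated autonomous drive whose second trial splits into a
calm highway part, a 1-min transition and a dynamic country-road part, and a
15-min recovery.  The gastric slow wave is modelled phenomenologically as a
phase-continuous sinusoid near 3 cpm with 100-500 µV amplitude; nausea
episodes raise the amplitude (with a linear ramp) and may shift the dominant
frequency into the tachygastric range.  Autonomic channels (GSR, heart rate),
motion artifacts, A/D quantization and a button-press point process tied to
the episodes complete the session, so every downstream analysis stage can be
exercised against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .preprocess import AcquisitionSpec, Annotation, EGGRecording, SegmentMap

__all__ = [
    "ButtonEvents",
    "EpisodeSpec",
    "SessionBundle",
    "SimConfig",
    "WristbandSeries",
    "cohort_configs",
    "generate_egg",
    "generate_session",
    "inject_artifact",
    "segment_map",
]

#: Linear amplitude ramp at episode onset/offset, seconds.
EPISODE_RAMP_S = 30.0


@dataclass(frozen=True)
class EpisodeSpec:
    """One nausea episode injected into the driving trial.

    ``amp_gain`` multiplies the slow-wave amplitude, ``freq_shift_cpm`` adds
    to the slow-wave frequency (tachygastria when positive), and
    ``press_rate_per_min`` drives the button-press process while the episode
    is active.
    """

    start_s: float
    end_s: float
    amp_gain: float = 2.0
    freq_shift_cpm: float = 0.0
    press_rate_per_min: float = 3.0

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError("episode must have end > start")
        if self.amp_gain < 1.0:
            raise ValueError("amp_gain must be >= 1")
        if self.press_rate_per_min < 0:
            raise ValueError("press_rate_per_min must be >= 0")


@dataclass(frozen=True)
class ButtonEvents:
    """Sorted nausea-report button-press timestamps in session seconds."""

    timestamps: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        ts = tuple(float(t) for t in self.timestamps)
        if any(t < 0 for t in ts):
            raise ValueError("button timestamps must be non-negative")
        if any(b < a for a, b in zip(ts, ts[1:])):
            raise ValueError("button timestamps must be sorted")
        object.__setattr__(self, "timestamps", ts)

    def __len__(self) -> int:
        return len(self.timestamps)

    def count_in(self, start_s: float, end_s: float) -> int:
        return sum(start_s <= t < end_s for t in self.timestamps)


@dataclass(frozen=True)
class WristbandSeries:
    """One wristband channel: times in seconds plus values (µS for GSR, bpm for HR)."""

    times: np.ndarray
    values: np.ndarray
    units: str

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape:
            raise ValueError("times and values must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(v)):
            raise ValueError("values must be finite")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def segment_stats(self, start_s: float, end_s: float) -> tuple[float, float]:
        """Mean and SD of the samples in ``[start_s, end_s)``."""
        sel = (self.times >= start_s) & (self.times < end_s)
        vals = self.values[sel]
        if vals.size == 0:
            return (float("nan"), float("nan"))
        return (float(vals.mean()), float(vals.std(ddof=1)) if vals.size > 1 else 0.0)


@dataclass(frozen=True)
class SimConfig:
    """Everything needed to generate one deterministic synthetic session."""

    seed: int = 0
    fs: float = 2.0
    trial_durations: tuple[float, float, float] = (900.0, 900.0, 900.0)
    part_split: tuple[float, float, float] = (420.0, 60.0, 420.0)
    f0_cpm: float = 3.0
    amp_uv: float = 200.0
    tachy_shift_cpm: float = 0.0
    episodes: tuple[EpisodeSpec, ...] = ()
    noise_sd_uv: float = 10.0
    wander_amp_uv: float = 0.0
    wander_freq_hz: float = 0.005
    artifact_specs: tuple[tuple[tuple[float, float], float], ...] = ()
    button_lead_s: float = 60.0
    button_jitter_sd_s: float = 30.0
    quantization_bits: int = 16
    n_channels: int = 3
    # wristband emulation: typical wearable rates and mild trial trends
    gsr_fs: float = 4.0
    hr_fs: float = 1.0
    gsr_base_us: float = 2.0
    gsr_trial_drift_us: float = 0.5
    gsr_noise_sd_us: float = 0.05
    hr_base_bpm: float = 70.0
    hr_trial2_delta_bpm: float = 8.0
    hr_noise_sd_bpm: float = 2.0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if any(d <= 0 for d in self.trial_durations):
            raise ValueError("trial durations must be positive")
        if not 1.0 < self.f0_cpm < 10.0:
            raise ValueError("f0_cpm must lie in (1, 10) cpm")
        if self.amp_uv <= 0:
            raise ValueError("amp_uv must be positive")
        seg = segment_map(self)
        lo, hi = seg.trial2
        for ep in self.episodes:
            if ep.start_s < lo or ep.end_s > hi:
                raise ValueError(
                    f"episode [{ep.start_s}, {ep.end_s}) outside the driving trial [{lo}, {hi})"
                )

    @property
    def acq(self) -> AcquisitionSpec:
        return AcquisitionSpec(fs=self.fs, resolution_bits=self.quantization_bits)


def segment_map(config: SimConfig) -> SegmentMap:
    """Session layout implied by the configured trial durations and part split."""
    d1, d2, d3 = config.trial_durations
    a, tr, b = config.part_split
    if abs((a + tr + b) - d2) > 1e-9:
        raise ValueError("part_split must sum to the trial-2 duration")
    t0 = 0.0
    return SegmentMap(
        trial1=(t0, d1),
        trial2A=(d1, d1 + a),
        transition=(d1 + a, d1 + a + tr),
        trial2B=(d1 + a + tr, d1 + d2),
        trial3=(d1 + d2, d1 + d2 + d3),
    )


@dataclass(frozen=True)
class SessionBundle:
    """One complete synthetic session plus its ground truth."""

    egg: EGGRecording
    gsr: WristbandSeries
    hr: WristbandSeries
    buttons: ButtonEvents
    segments: SegmentMap
    truth: tuple[EpisodeSpec, ...]


def _ramped_gain(t: np.ndarray, episodes: tuple[EpisodeSpec, ...], ramp_s: float) -> np.ndarray:
    """Multiplicative amplitude profile: 1 outside episodes, amp_gain inside,
    with linear ramps of ``ramp_s`` placed inside the episode window."""
    g = np.ones_like(t)
    for ep in episodes:
        ramp = min(ramp_s, (ep.end_s - ep.start_s) / 2.0)
        up = np.clip((t - ep.start_s) / max(ramp, 1e-9), 0.0, 1.0)
        down = np.clip((ep.end_s - t) / max(ramp, 1e-9), 0.0, 1.0)
        prof = np.where((t >= ep.start_s) & (t < ep.end_s), np.minimum(up, down), 0.0)
        g += (ep.amp_gain - 1.0) * prof
    return g


def _freq_profile(t: np.ndarray, config: SimConfig) -> np.ndarray:
    """Instantaneous slow-wave frequency in Hz (shared by all electrodes)."""
    f = np.full_like(t, config.f0_cpm / 60.0)
    if config.tachy_shift_cpm:
        b0, b1 = segment_map(config).trial2B
        f += (config.tachy_shift_cpm / 60.0) * ((t >= b0) & (t < b1))
    for ep in config.episodes:
        if ep.freq_shift_cpm:
            f += (ep.freq_shift_cpm / 60.0) * ((t >= ep.start_s) & (t < ep.end_s))
    return f


def _quantize(x: np.ndarray, acq: AcquisitionSpec) -> np.ndarray:
    step = acq.quant_step_uv
    fullscale = acq.full_scale_uv
    return np.clip(np.round(x / step) * step, -fullscale, fullscale)


def generate_egg(config: SimConfig) -> EGGRecording:
    """Generate the 3-channel EGG recording for one session.

    All channels see one gastric source: they share the instantaneous
    frequency profile (episode/tachygastric shifts included) but carry
    independent random phases and independent additive white Gaussian noise.
    The phase is accumulated by integrating the frequency profile so episode
    frequency shifts are phase-continuous.  Samples are quantized to the
    configured bit depth over a fixed ±1000 µV input-referred range.
    Deterministic for a fixed config (seed included).
    """
    rng = np.random.default_rng(config.seed)
    seg = segment_map(config)
    n = int(round(seg.span[1] * config.fs))
    t = np.arange(n) / config.fs

    f_inst = _freq_profile(t, config)
    phase = 2.0 * np.pi * np.cumsum(f_inst) / config.fs
    gain = _ramped_gain(t, config.episodes, EPISODE_RAMP_S)

    channels = np.empty((config.n_channels, n))
    phases = rng.uniform(0.0, 2.0 * np.pi, size=config.n_channels)
    for ch in range(config.n_channels):
        x = config.amp_uv * gain * np.sin(phase + phases[ch])
        if config.wander_amp_uv:
            x = x + config.wander_amp_uv * np.sin(
                2.0 * np.pi * config.wander_freq_hz * t + rng.uniform(0, 2 * np.pi)
            )
        if config.noise_sd_uv:
            x = x + rng.normal(0.0, config.noise_sd_uv, size=n)
        channels[ch] = x

    rec = EGGRecording(samples=channels, acq=config.acq)
    for interval, magnitude in config.artifact_specs:
        rec = inject_artifact(rec, interval, magnitude)
    rec.samples = _quantize(rec.samples, config.acq)
    return rec


def inject_artifact(
    recording: EGGRecording,
    interval: tuple[float, float],
    magnitude_uv: float,
    channel: int | None = None,
    kind: str = "artifact",
) -> EGGRecording:
    """Superimpose a high-amplitude motion transient and annotate the interval.

    The transient is a deterministic Tukey-windowed 0.25 Hz oscillation of the
    given peak magnitude, on one channel or (``channel=None``) all channels.
    A zero-magnitude call still records the annotation, mirroring a manual
    markup of a visually suspect stretch.
    """
    from scipy.signal.windows import tukey

    start_s, end_s = interval
    t0 = recording.start_time
    if start_s < t0 or end_s > t0 + recording.duration_s or end_s <= start_s:
        raise ValueError(
            f"artifact interval [{start_s}, {end_s}) outside recording span "
            f"[{t0}, {t0 + recording.duration_s})"
        )
    out = recording.copy()
    sl = out.sample_slice(start_s, end_s)
    nseg = sl.stop - sl.start
    if nseg > 0 and magnitude_uv != 0.0:
        tt = np.arange(nseg) / out.acq.fs
        burst = magnitude_uv * tukey(nseg, alpha=0.5) * np.cos(2 * np.pi * 0.25 * tt)
        if channel is None:
            out.samples[:, sl] += burst
        else:
            out.samples[channel, sl] += burst
    out.annotations.append(Annotation(start_s, end_s, channel=channel, kind=kind))
    return out


def _wristband(config: SimConfig, seg: SegmentMap, rng: np.random.Generator) -> tuple[WristbandSeries, WristbandSeries]:
    span = seg.span[1]
    # GSR: tonic level drifting upward trial over trial (arousal accumulates)
    tg = np.arange(int(round(span * config.gsr_fs))) / config.gsr_fs
    level = np.full_like(tg, config.gsr_base_us)
    for i, (name, (s0, s1)) in enumerate(
        [("t1", seg.trial1), ("t2", seg.trial2), ("t3", seg.trial3)]
    ):
        level += config.gsr_trial_drift_us * i * ((tg >= s0) & (tg < s1))
    gsr_vals = level + rng.normal(0.0, config.gsr_noise_sd_us, size=tg.size)
    gsr = WristbandSeries(times=tg, values=np.maximum(gsr_vals, 0.01), units="uS")

    # HR: elevated during the driving trial
    th = np.arange(int(round(span * config.hr_fs))) / config.hr_fs
    hr_level = np.full_like(th, config.hr_base_bpm)
    s0, s1 = seg.trial2
    hr_level += config.hr_trial2_delta_bpm * ((th >= s0) & (th < s1))
    hr_vals = hr_level + rng.normal(0.0, config.hr_noise_sd_bpm, size=th.size)
    hr = WristbandSeries(times=th, values=np.maximum(hr_vals, 30.0), units="bpm")
    return gsr, hr


def _buttons(config: SimConfig, seg: SegmentMap, rng: np.random.Generator) -> ButtonEvents:
    """Rate-modulated press process: the first press of each episode leads the
    amplitude increase by ~button_lead_s (jittered), further presses arrive as
    a Poisson process at press_rate until the episode ends."""
    presses: list[float] = []
    lo, hi = seg.trial2
    for ep in config.episodes:
        if ep.press_rate_per_min <= 0:
            continue
        first = ep.start_s - config.button_lead_s + rng.normal(0.0, config.button_jitter_sd_s)
        first = min(max(first, lo), ep.end_s)
        presses.append(first)
        rate_hz = ep.press_rate_per_min / 60.0
        t = first
        while True:
            t = t + rng.exponential(1.0 / rate_hz)
            if t >= ep.end_s:
                break
            presses.append(t)
    return ButtonEvents(timestamps=tuple(sorted(presses)))


def generate_session(config: SimConfig) -> SessionBundle:
    """Generate a full synthetic session: EGG + GSR + HR + button presses.

    The EGG stream is produced by :func:`generate_egg` under the same seed;
    wristband channels and the press process draw from an independent stream
    derived from the seed, so the EGG signal is unchanged by wristband
    parameters.
    """
    seg = segment_map(config)
    egg = generate_egg(config)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0xB10)))
    gsr, hr = _wristband(config, seg, rng)
    buttons = _buttons(config, seg, rng)
    return SessionBundle(
        egg=egg, gsr=gsr, hr=hr, buttons=buttons, segments=seg, truth=tuple(config.episodes)
    )


def cohort_configs(
    n_subjects: int,
    seed: int,
    template: SimConfig | None = None,
    f0_sd_cpm: float = 0.3,
    amp_range_uv: tuple[float, float] = (150.0, 300.0),
) -> list[SimConfig]:
    """Per-subject configs with realistic between-subject variability.

    Each subject gets an independent seed, a slow-wave frequency drawn
    N(f0, f0_sd) clipped to the healthy 2-4 cpm range, and an amplitude drawn
    uniformly from ``amp_range_uv`` (inside the physiological 100-500 µV
    span).  Episode/shift settings are inherited from the template, so the
    cohort shares the study manipulation while differing physiologically.
    """
    template = template or SimConfig()
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xC040)))
    subject_seeds = rng.integers(0, 2**31 - 1, size=n_subjects)
    f0s = np.clip(rng.normal(template.f0_cpm, f0_sd_cpm, size=n_subjects), 2.0, 4.0)
    amps = rng.uniform(*amp_range_uv, size=n_subjects)
    return [
        replace(template, seed=int(s), f0_cpm=float(f0), amp_uv=float(a))
        for s, f0, a in zip(subject_seeds, f0s, amps)
    ]
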