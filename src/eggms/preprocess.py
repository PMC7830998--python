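"""Preprocessing of cutaneous EGG recordings.

The gastric slow wave lives in a narrow band around 3 cpm, while skin-electrode
recordings at microvolt amplitudes pick up DC drift, respiration and motion
transients.  The preprocessing chain is therefore: zero-phase band-pass
filtering to the 1-10 cpm gastric band, manual-annotation-driven artifact
exclusion, and selection of the channel with the fewest artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "AcquisitionSpec",
    "Annotation",
    "EGGRecording",
    "SegmentMap",
    "BAND_HZ",
    "bandpass_filter",
    "butterworth_bandpass_gain",
    "edge_guard",
    "exclude_artifacts",
    "select_channel",
]

#: Analysis band in Hz: 1 cpm to 10 cpm.
BAND_HZ = (1.0 / 60.0, 10.0 / 60.0)

#: Butterworth order of the band-pass transfer function (6 poles).
FILTER_ORDER = 6

#: Width of the filter edge-transient region excluded from feature segments.
EDGE_GUARD_S = 60.0


@dataclass(frozen=True)
class AcquisitionSpec:
    """Acquisition front-end parameters.

    Defaults mirror a clinical 3-channel EGG amplifier: analog gain 1000,
    2 Hz sampling and 16-bit A/D conversion.
    """

    fs: float = 2.0
    gain: float = 1000.0
    resolution_bits: int = 16
    #: Full-scale range referred to input, in microvolt (one side).
    full_scale_uv: float = 1000.0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.gain <= 0:
            raise ValueError(f"gain must be positive, got {self.gain}")

    @property
    def quant_step_uv(self) -> float:
        """Quantization step in microvolt referred to input."""
        return 2.0 * self.full_scale_uv / 2**self.resolution_bits


@dataclass(frozen=True)
class Annotation:
    """Half-open interval ``[start_s, end_s)`` marking samples to exclude.

    ``channel`` is a 0-based index, or ``None`` when the interval applies to
    every channel.  ``kind`` distinguishes manually annotated motion artifacts
    from filter edge transients and A/D saturation runs.
    """

    start_s: float
    end_s: float
    channel: int | None = None
    kind: str = "artifact"

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError(
                f"annotation interval must be non-empty, got [{self.start_s}, {self.end_s})"
            )


@dataclass
class EGGRecording:
    """Multi-channel EGG time series in microvolt.

    ``samples`` has shape ``(n_channels, n_samples)``.  Masked (excluded)
    samples are NaN; the invariant is that NaN appears only inside annotated
    intervals.
    """

    samples: np.ndarray
    acq: AcquisitionSpec = field(default_factory=AcquisitionSpec)
    annotations: list[Annotation] = field(default_factory=list)
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.acq.fs

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.acq.fs

    def copy(self) -> "EGGRecording":
        return EGGRecording(
            samples=self.samples.copy(),
            acq=self.acq,
            annotations=list(self.annotations),
            start_time=self.start_time,
        )

    def sample_slice(self, start_s: float, end_s: float) -> slice:
        """Sample-index slice of the half-open time interval ``[start_s, end_s)``."""
        fs = self.acq.fs
        i0 = int(np.ceil(round((start_s - self.start_time) * fs, 9)))
        i1 = int(np.ceil(round((end_s - self.start_time) * fs, 9)))
        return slice(max(i0, 0), min(i1, self.n_samples))

    def annotation_mask(self, channel: int, kinds: tuple[str, ...] | None = None) -> np.ndarray:
        """Boolean mask of annotated samples on ``channel``.

        ``kinds`` restricts to the given annotation kinds; ``None`` means all.
        """
        mask = np.zeros(self.n_samples, dtype=bool)
        for ann in self.annotations:
            if ann.channel is not None and ann.channel != channel:
                continue
            if kinds is not None and ann.kind not in kinds:
                continue
            mask[self.sample_slice(ann.start_s, ann.end_s)] = True
        return mask


@dataclass(frozen=True)
class SegmentMap:
    """Named half-open trial intervals in seconds from session start.

    The session layout is: a baseline trial, a driving trial split into a calm
    part A, a transition, and a dynamic part B, and a recovery trial.
    """

    trial1: tuple[float, float]
    trial2A: tuple[float, float]
    transition: tuple[float, float]
    trial2B: tuple[float, float]
    trial3: tuple[float, float]

    def __post_init__(self) -> None:
        ivs = [self.trial1, self.trial2A, self.transition, self.trial2B, self.trial3]
        for (a0, a1), (b0, b1) in zip(ivs, ivs[1:]):
            if a1 <= a0 or b1 <= b0:
                raise ValueError("segment intervals must be non-empty")
            if b0 < a1:
                raise ValueError("segment intervals must be ordered and non-overlapping")

    @property
    def trial2(self) -> tuple[float, float]:
        """The full driving trial, parts A and B plus the transition."""
        return (self.trial2A[0], self.trial2B[1])

    def named(self) -> dict[str, tuple[float, float]]:
        return {
            "trial1": self.trial1,
            "trial2A": self.trial2A,
            "transition": self.transition,
            "trial2B": self.trial2B,
            "trial3": self.trial3,
        }

    @property
    def span(self) -> tuple[float, float]:
        return (self.trial1[0], self.trial3[1])


def _design_sos(fs: float) -> np.ndarray:
    # butter(N=3, 'bandpass') has a 6-pole (6th order) transfer function with
    # -3 dB single-pass points at the band edges.
    return signal.butter(FILTER_ORDER // 2, BAND_HZ, btype="bandpass", fs=fs, output="sos")


def butterworth_bandpass_gain(freq_hz: np.ndarray | float, passes: int = 2) -> np.ndarray | float:
    """Analytic magnitude response of the band-pass chain at ``freq_hz``.

    Closed form for an order-6 Butterworth band-pass with -3 dB edges at the
    gastric band limits; ``passes=2`` gives the forward-backward (zero-phase)
    amplitude response, which is the single-pass response squared.
    """
    f = np.asarray(freq_hz, dtype=float)
    f1, f2 = BAND_HZ
    x = (f**2 - f1 * f2) / (f * (f2 - f1))
    single_sq = 1.0 / (1.0 + x ** (2 * (FILTER_ORDER // 2)))
    return single_sq ** (passes / 2.0)


def bandpass_filter(recording: EGGRecording) -> EGGRecording:
    """Zero-phase 6th-order Butterworth band-pass, 1-10 cpm, per channel.

    Forward-backward application cancels phase distortion so event timing is
    preserved; the magnitude response is squared, leaving amplitude ~0.5 at
    the nominal cutoffs.  Edges are handled by reflecting the signal.

    Raises
    ------
    ValueError
        If the recording is shorter than the filter warm-up length.
    """
    sos = _design_sos(recording.acq.fs)
    out = recording.copy()
    filtered = np.empty_like(out.samples)
    for ch in range(out.n_channels):
        x = out.samples[ch]
        if np.isnan(x).any():
            raise ValueError(
                "bandpass_filter expects unmasked samples; run it before exclude_artifacts"
            )
        try:
            filtered[ch] = signal.sosfiltfilt(sos, x, padtype="even")
        except ValueError as err:
            raise ValueError(
                f"recording too short for zero-phase filtering "
                f"({recording.n_samples} samples): {err}"
            ) from err
    out.samples = filtered
    return out


def edge_guard(recording: EGGRecording, guard_s: float = EDGE_GUARD_S) -> EGGRecording:
    """Annotate the filter edge-transient regions at both ends of the recording.

    The first and last ``guard_s`` seconds are flagged (kind ``"edge"``) so
    downstream feature segments skip them; channel selection ignores edge
    annotations since they affect all channels equally.
    """
    out = recording.copy()
    t0 = recording.start_time
    t1 = t0 + recording.duration_s
    if 2 * guard_s >= recording.duration_s:
        raise ValueError("edge guard would exclude the whole recording")
    out.annotations.append(Annotation(t0, t0 + guard_s, channel=None, kind="edge"))
    out.annotations.append(Annotation(t1 - guard_s, t1, channel=None, kind="edge"))
    return out


def exclude_artifacts(recording: EGGRecording) -> tuple[EGGRecording, dict[int, int]]:
    """Mask annotated samples (all kinds) with NaN.

    Masked samples are excluded from every downstream statistic rather than
    interpolated.  Returns the masked recording and the per-channel count of
    newly masked clean samples.  Idempotent: applying twice equals once.
    """
    out = recording.copy()
    counts: dict[int, int] = {}
    for ch in range(out.n_channels):
        mask = out.annotation_mask(ch)
        newly = mask & ~np.isnan(out.samples[ch])
        counts[ch] = int(newly.sum())
        out.samples[ch, mask] = np.nan
    return out, counts


def select_channel(recording: EGGRecording) -> int:
    """Index (0-based) of the channel with the fewest annotated artifact seconds.

    Only ``"artifact"`` and ``"saturation"`` annotations count (edge
    transients hit all channels equally).  Ties break to the lowest index.

    Raises
    ------
    ValueError
        If every channel is fully annotated (no usable channel).
    """
    if recording.n_channels < 1:
        raise ValueError("recording has no channels")
    totals = []
    for ch in range(recording.n_channels):
        mask = recording.annotation_mask(ch, kinds=("artifact", "saturation"))
        totals.append(mask.sum() / recording.acq.fs)
    totals = np.asarray(totals)
    if np.all(totals >= recording.duration_s):
        raise ValueError("all channels fully annotated; no usable channel")
    return int(np.argmin(totals))
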