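"""Per-segment spectral sickness indicators.

Six indicators summarise one EGG segment: RMS amplitude, median frequency
(MF), dominant frequency (DF, the location of the PSD maximum MFM), the PSD
maximum itself, the crest factor of the PSD (CF, peak over effective value —
drops as spectral power disperses) and FSD, the percentage of analysis-band
bins whose PSD exceeds a quarter of the maximum (rises with dispersion).
DF shifts above the normal 2-4 cpm range indicate tachygastria; CF and FSD
move with spectral dispersion during nausea.

PSD estimation is an averaged modified periodogram (Hann window, 512-sample
segments = 256 s at 2 Hz, 50% overlap), giving ~0.23 cpm resolution.  Masked
(NaN) samples never enter the estimate: only clean contiguous stretches long
enough for a full window contribute.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .preprocess import BAND_HZ, AcquisitionSpec

__all__ = [
    "PSDEstimate",
    "SpectralFeatures",
    "compute_psd",
    "compute_features",
    "spectral_indicators",
]

#: Welch segment length in samples (256 s at 2 Hz -> ~0.23 cpm resolution).
NPERSEG = 512
MIN_CLEAN_S = 300.0


@dataclass(frozen=True)
class PSDEstimate:
    """One-sided PSD on a regular frequency grid, with the analysis band."""

    freqs: np.ndarray
    power: np.ndarray
    band: tuple[float, float] = BAND_HZ

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        p = np.asarray(self.power, dtype=float)
        if f.shape != p.shape:
            raise ValueError("freqs and power must have equal shape")
        if np.any(np.diff(f) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if np.any(p < 0):
            raise ValueError("PSD values must be non-negative")
        object.__setattr__(self, "freqs", f)
        object.__setattr__(self, "power", p)

    def band_selection(self) -> tuple[np.ndarray, np.ndarray]:
        """Frequencies and PSD values restricted to the analysis band (inclusive)."""
        lo, hi = self.band
        sel = (self.freqs >= lo - 1e-12) & (self.freqs <= hi + 1e-12)
        return self.freqs[sel], self.power[sel]


@dataclass(frozen=True)
class SpectralFeatures:
    """The six indicators for one segment.

    Frequencies are reported in cpm; ``mfm`` is in µV²/Hz; ``fsd_pct`` is a
    percentage of analysis-band bins.
    """

    rms_uv: float
    mf_cpm: float
    df_cpm: float
    mfm: float
    cf: float
    fsd_pct: float

    def as_dict(self) -> dict[str, float]:
        return {
            "rms_uV": self.rms_uv,
            "mf_cpm": self.mf_cpm,
            "df_cpm": self.df_cpm,
            "mfm": self.mfm,
            "cf": self.cf,
            "fsd_pct": self.fsd_pct,
        }


def _clean_stretches(x: np.ndarray) -> list[np.ndarray]:
    """Contiguous runs of non-NaN samples."""
    isfin = np.isfinite(x)
    if not isfin.any():
        return []
    edges = np.flatnonzero(np.diff(isfin.astype(np.int8)))
    bounds = np.concatenate(([0], edges + 1, [x.size]))
    return [
        x[a:b]
        for a, b in zip(bounds[:-1], bounds[1:])
        if isfin[a]
    ]


def compute_psd(
    segment: np.ndarray,
    acq: AcquisitionSpec,
    nperseg: int = NPERSEG,
    band: tuple[float, float] = BAND_HZ,
) -> PSDEstimate:
    """Averaged-periodogram PSD over the clean stretches of ``segment``.

    Each clean stretch long enough for at least one full window contributes
    Hann-windowed half-overlapping periodograms; stretches are averaged with
    weights equal to their window counts, which reduces to plain Welch when
    the segment has no masked samples.

    Raises
    ------
    ValueError
        If less than 300 s of clean data, or no clean stretch spans a full
        window.
    """
    x = np.asarray(segment, dtype=float)
    fs = acq.fs
    stretches = _clean_stretches(x)
    clean_s = sum(s.size for s in stretches) / fs
    if clean_s < MIN_CLEAN_S:
        raise ValueError(
            f"insufficient clean data: {clean_s:.0f} s < {MIN_CLEAN_S:.0f} s required"
        )
    usable = [s for s in stretches if s.size >= nperseg]
    if not usable:
        raise ValueError(
            f"no clean stretch spans a full {nperseg}-sample analysis window"
        )
    noverlap = nperseg // 2
    acc = None
    total_w = 0
    freqs = None
    for s in usable:
        f, p = signal.welch(
            s, fs=fs, window="hann", nperseg=nperseg, noverlap=noverlap,
            detrend="constant", scaling="density",
        )
        nwin = 1 + (s.size - nperseg) // (nperseg - noverlap)
        acc = p * nwin if acc is None else acc + p * nwin
        total_w += nwin
        freqs = f
    return PSDEstimate(freqs=freqs, power=acc / total_w, band=band)


def spectral_indicators(psd: PSDEstimate) -> dict[str, float]:
    """MFM, DF, MF, CF and FSD from a PSD estimate, band-restricted.

    DF ties break to the lowest frequency; MF is the first frequency at which
    the cumulative band power reaches half the total band power; CF is the
    band maximum over the RMS of the band PSD values; FSD is the percentage
    of band bins exceeding a quarter of the maximum.
    """
    freqs, power = psd.band_selection()
    if freqs.size == 0:
        raise ValueError("analysis band contains no PSD bins")
    if not np.any(power > 0):
        raise ValueError("all-zero PSD in the analysis band; indicators undefined")
    mfm = float(power.max())
    df_hz = float(freqs[int(np.argmax(power))])  # argmax takes the first max
    cum = np.cumsum(power)
    mf_hz = float(freqs[int(np.searchsorted(cum, 0.5 * cum[-1]))])
    cf = mfm / float(np.sqrt(np.mean(power**2)))
    fsd = 100.0 * float(np.count_nonzero(power > mfm / 4.0)) / freqs.size
    return {
        "mfm": mfm,
        "df_cpm": df_hz * 60.0,
        "mf_cpm": mf_hz * 60.0,
        "cf": cf,
        "fsd_pct": fsd,
    }


def compute_features(
    segment: np.ndarray,
    acq: AcquisitionSpec,
    nperseg: int = NPERSEG,
    band: tuple[float, float] = BAND_HZ,
) -> SpectralFeatures:
    """All six indicators for one clean-masked segment of the filtered signal.

    RMS is computed in the time domain over clean samples; the five spectral
    indicators come from :func:`compute_psd` + :func:`spectral_indicators`.
    """
    x = np.asarray(segment, dtype=float)
    clean = x[np.isfinite(x)]
    if clean.size == 0 or not np.any(clean != 0):
        raise ValueError("all-zero or fully masked segment; features undefined")
    rms = float(np.sqrt(np.mean(clean**2)))
    psd = compute_psd(x, acq, nperseg=nperseg, band=band)
    ind = spectral_indicators(psd)
    return SpectralFeatures(
        rms_uv=rms,
        mf_cpm=ind["mf_cpm"],
        df_cpm=ind["df_cpm"],
        mfm=ind["mfm"],
        cf=ind["cf"],
        fsd_pct=ind["fsd_pct"],
    )
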