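"""EEG-style spectral analysis of the model output.

Standard pipeline: zero-phase Butterworth band-pass, Welch averaged
periodogram, then alpha-band (8-13 Hz) summaries — peak power density,
dominant frequency and integrated power per 1-Hz sub-band.  For
repeated stochastic runs the per-repeat PSDs are averaged; averaging
traces first would cancel oscillations with random phase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import ConfigurationError

__all__ = [
    "SpectralConfig",
    "SpectralSummary",
    "bandpass",
    "welch_psd",
    "alpha_summary",
    "summarize_traces",
]


@dataclass(frozen=True)
class SpectralConfig:
    """Filter, PSD and band-summary settings.

    fs : sampling rate, Hz
    band_low, band_high : Butterworth passband edges, Hz
    alpha_low, alpha_high : alpha-band edges, Hz
    filter_order : Butterworth order (applied forward-backward)
    welch_segment : Welch segment length, s (spectral resolution 1/segment)
    welch_overlap : fractional segment overlap
    window : taper name, anything scipy.signal.get_window accepts
    """

    fs: float = 1000.0
    band_low: float = 1.0
    band_high: float = 40.0
    alpha_low: float = 8.0
    alpha_high: float = 13.0
    filter_order: int = 4
    welch_segment: float = 4.0
    welch_overlap: float = 0.5
    window: str = "hann"

    def __post_init__(self):
        if not 0 < self.band_low < self.band_high < self.fs / 2:
            raise ConfigurationError(
                f"need 0 < band_low < band_high < fs/2, got "
                f"({self.band_low}, {self.band_high}) at fs={self.fs}"
            )
        if not (self.band_low <= self.alpha_low < self.alpha_high <= self.band_high):
            raise ConfigurationError(
                f"alpha band ({self.alpha_low}, {self.alpha_high}) must sit "
                f"inside the passband ({self.band_low}, {self.band_high})"
            )
        if not 0 <= self.welch_overlap < 1:
            raise ConfigurationError(f"welch_overlap must be in [0, 1), got {self.welch_overlap}")

    @property
    def nperseg(self) -> int:
        return int(round(self.welch_segment * self.fs))

    @property
    def noverlap(self) -> int:
        return int(round(self.nperseg * self.welch_overlap))

    def sos(self) -> np.ndarray:
        return signal.butter(self.filter_order, [self.band_low, self.band_high],
                             btype="bandpass", fs=self.fs, output="sos")


@dataclass
class SpectralSummary:
    """Alpha-band readouts of a (repeat-averaged) power spectrum."""

    freqs: np.ndarray          # frequency grid, Hz
    psd: np.ndarray            # power spectral density, mV^2/Hz
    peak_power: float          # max PSD inside the alpha band, mV^2/Hz
    dominant_freq: float       # frequency of that maximum, Hz
    subband_powers: np.ndarray # integrated power per 1-Hz sub-band, mV^2
    subband_edges: np.ndarray  # sub-band edge frequencies, Hz
    total_alpha_power: float   # integrated power over the full band, mV^2


def bandpass(trace: np.ndarray, cfg: SpectralConfig) -> np.ndarray:
    """Zero-phase Butterworth band-pass; output length equals input."""
    trace = np.asarray(trace, dtype=float)
    if trace.shape[-1] <= 3 * (2 * cfg.filter_order + 1):
        raise ConfigurationError(
            f"trace of length {trace.shape[-1]} too short for an order-"
            f"{cfg.filter_order} forward-backward filter"
        )
    return signal.sosfiltfilt(cfg.sos(), trace, axis=-1)


def welch_psd(trace: np.ndarray, cfg: SpectralConfig):
    """One-sided Welch PSD on a grid of resolution 1/welch_segment Hz.

    Raises :class:`ConfigurationError` when the trace is shorter than
    one segment (simulate longer, or shorten ``welch_segment``).
    """
    trace = np.asarray(trace, dtype=float)
    if trace.shape[-1] < cfg.nperseg:
        raise ConfigurationError(
            f"trace length {trace.shape[-1]} is shorter than one Welch segment "
            f"({cfg.nperseg} samples); extend the simulation or reduce welch_segment"
        )
    freqs, psd = signal.welch(trace, fs=cfg.fs, window=cfg.window,
                              nperseg=cfg.nperseg, noverlap=cfg.noverlap,
                              detrend="constant", axis=-1)
    return freqs, psd


def _band_integral(freqs, psd, lo, hi):
    """Trapezoidal integral of the PSD over [lo, hi], with the edge
    values obtained by linear interpolation so consecutive bins tile
    exactly."""
    inner = (freqs > lo) & (freqs < hi)
    f = np.concatenate(([lo], freqs[inner], [hi]))
    p = np.concatenate(([np.interp(lo, freqs, psd)], psd[inner],
                        [np.interp(hi, freqs, psd)]))
    return np.trapezoid(p, f)


def alpha_summary(freqs: np.ndarray, psd: np.ndarray, cfg: SpectralConfig) -> SpectralSummary:
    """Summarize a PSD over the alpha band.

    Peak power is the maximum density on the closed band; the dominant
    frequency is its location (ties resolved to the lowest frequency,
    which is what ``argmax`` on an ascending grid returns).  Sub-band
    powers are trapezoidal integrals over consecutive 1-Hz bins.
    """
    freqs = np.asarray(freqs, dtype=float)
    psd = np.asarray(psd, dtype=float)
    if freqs[0] > cfg.alpha_low or freqs[-1] < cfg.alpha_high:
        raise ConfigurationError(
            f"frequency grid [{freqs[0]}, {freqs[-1]}] does not cover the "
            f"alpha band [{cfg.alpha_low}, {cfg.alpha_high}]"
        )
    in_band = (freqs >= cfg.alpha_low) & (freqs <= cfg.alpha_high)
    band_psd = psd[in_band]
    band_freqs = freqs[in_band]
    i_max = int(np.argmax(band_psd))
    edges = np.arange(np.floor(cfg.alpha_low), np.ceil(cfg.alpha_high) + 0.5)
    edges = np.clip(edges, cfg.alpha_low, cfg.alpha_high)
    subbands = np.array([
        _band_integral(freqs, psd, edges[j], edges[j + 1])
        for j in range(len(edges) - 1)
    ])
    return SpectralSummary(
        freqs=freqs, psd=psd,
        peak_power=float(band_psd[i_max]),
        dominant_freq=float(band_freqs[i_max]),
        subband_powers=subbands,
        subband_edges=edges,
        total_alpha_power=float(_band_integral(freqs, psd, cfg.alpha_low, cfg.alpha_high)),
    )


def summarize_traces(traces: np.ndarray, cfg: SpectralConfig) -> SpectralSummary:
    """Full pipeline for a stack of repeat traces.

    Each repeat is band-pass filtered and Welch-transformed; the
    per-repeat PSDs are averaged and then summarized over the alpha
    band.
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    filtered = bandpass(traces, cfg)
    freqs, psds = welch_psd(filtered, cfg)
    mean_psd = psds.mean(axis=0) if psds.ndim > 1 else psds
    return alpha_summary(freqs, mean_psd, cfg)
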