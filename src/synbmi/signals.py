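"""Feature-extraction chains for raw neural and EMG waveforms.

Implements the offline preprocessing used throughout the pipeline:

* EMG envelope extraction: anti-alias low-pass (800 Hz) -> downsample to
  2000 Hz -> band-pass 100-500 Hz -> full-wave rectification -> low-pass
  6 Hz, clipped at zero.
* Daily peak normalization of envelopes.
* Threshold-crossing detection at a multiple (default -4.5) of each
  channel's RMS over a calibration segment, with 1 ms refractory merging.
* Active-channel selection (>= 1 crossing/s on average by default).
* Spiking-band power (SBP): 300-1000 Hz band power averaged into 20 ms
  bins.  "Power" is the per-bin mean absolute value by default (the common
  low-bandwidth SBP convention); mean square is available as an option.
* Artifact masking: reward-pump windows are flagged, never interpolated,
  so lagged designs can drop any row that touches them.

All filters are 4th-order Butterworth applied forward-backward
(zero-phase); this is offline analysis, so no phase distortion is
introduced and filter order requirements stay modest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .session import BinnedSession

logger = logging.getLogger(__name__)

EMG_TARGET_RATE = 2000.0
EMG_ANTIALIAS_HZ = 800.0
EMG_BAND = (100.0, 500.0)
EMG_ENVELOPE_LP_HZ = 6.0
SBP_BAND = (300.0, 1000.0)
FILTER_ORDER = 4


@dataclass
class WaveformBlock:
    """A block of multichannel raw waveform data (channels x samples)."""

    samples: np.ndarray
    sampling_rate: float
    channel_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass
class CrossingEvents:
    """Per-channel threshold-crossing event times (seconds), sorted."""

    times: list[np.ndarray]
    thresholds: np.ndarray
    duration: float

    def counts(self) -> np.ndarray:
        return np.array([len(t) for t in self.times])


def _butter_sos(cutoff, fs: float, btype: str):
    return sps.butter(FILTER_ORDER, cutoff, btype=btype, fs=fs, output="sos")


def extract_emg_envelope(raw: WaveformBlock) -> WaveformBlock:
    """Run the EMG envelope chain; output is at 2000 Hz, nonnegative.

    Pipeline order: 800 Hz anti-alias low-pass, downsample to 2000 Hz
    (skipped when the input is already at 2000 Hz), 100-500 Hz band-pass,
    full-wave rectify, 6 Hz low-pass, clip at zero.
    """
    fs = raw.sampling_rate
    if fs < 1000.0:
        raise ValueError(
            f"input rate {fs} Hz is too low: the {EMG_BAND[0]:.0f}-"
            f"{EMG_BAND[1]:.0f} Hz band-pass is infeasible"
        )
    x = raw.samples
    if fs != EMG_TARGET_RATE:
        sos_aa = _butter_sos(EMG_ANTIALIAS_HZ, fs, "lowpass")
        x = sps.sosfiltfilt(sos_aa, x, axis=1)
        frac = Fraction(EMG_TARGET_RATE / fs).limit_denominator(1000)
        x = sps.resample_poly(x, frac.numerator, frac.denominator, axis=1)
        fs = EMG_TARGET_RATE
    sos_bp = _butter_sos(EMG_BAND, fs, "bandpass")
    x = sps.sosfiltfilt(sos_bp, x, axis=1)
    x = np.abs(x)
    sos_lp = _butter_sos(EMG_ENVELOPE_LP_HZ, fs, "lowpass")
    x = sps.sosfiltfilt(sos_lp, x, axis=1)
    x = np.clip(x, 0.0, None)
    return WaveformBlock(x, fs, raw.channel_labels)


def normalize_daily_peak(data: np.ndarray, day_ids=None,
                         time_axis: int = 0) -> np.ndarray:
    """Normalize each channel to its within-day peak, into [0, 1].

    ``data`` may be a binned T x E matrix (``time_axis=0``) or a
    channels x samples waveform (``time_axis=1``).  ``day_ids`` is an
    optional per-timepoint label vector; each day is normalized
    independently.  All-zero channels are left at zero with a warning.
    """
    data = np.asarray(data, dtype=float)
    if data.size and data.min() < 0:
        raise ValueError("normalize_daily_peak expects nonnegative input")
    x = np.moveaxis(data, time_axis, 0).copy()
    if day_ids is None:
        day_ids = np.zeros(x.shape[0], dtype=np.int64)
    day_ids = np.asarray(day_ids)
    if day_ids.shape[0] != x.shape[0]:
        raise ValueError("day_ids must have one entry per timepoint")
    for day in np.unique(day_ids):
        rows = day_ids == day
        peaks = x[rows].max(axis=0)
        zero = peaks == 0
        if np.any(zero):
            logger.warning(
                "normalize_daily_peak: %d all-zero channel(s) on day %r left at zero",
                int(zero.sum()), day)
            peaks = np.where(zero, 1.0, peaks)
        x[rows] = x[rows] / peaks
    return np.moveaxis(x, 0, time_axis)


def detect_threshold_crossings(raw: WaveformBlock,
                               rms_multiplier: float = -4.5,
                               calibration_seconds: float = 10.0,
                               refractory: float = 1e-3) -> CrossingEvents:
    """Detect threshold crossings per channel.

    The threshold is ``rms_multiplier`` times the channel RMS over the
    calibration segment (default: the first 10 s).  A negative multiplier
    detects downward crossings; a positive one detects upward crossings.
    Crossings within the refractory window (1 ms) are merged.
    """
    fs = raw.sampling_rate
    n_cal = int(round(calibration_seconds * fs))
    if n_cal > raw.n_samples:
        raise ValueError("calibration segment is longer than the recording")
    if n_cal < 1:
        raise ValueError("calibration segment must contain at least one sample")
    cal = raw.samples[:, :n_cal]
    rms = np.sqrt(np.mean(cal ** 2, axis=1))
    thresholds = rms_multiplier * rms

    times: list[np.ndarray] = []
    for ch in range(raw.n_channels):
        x = raw.samples[ch]
        thr = thresholds[ch]
        if rms_multiplier < 0:
            hit = (x[:-1] > thr) & (x[1:] <= thr)
        else:
            hit = (x[:-1] < thr) & (x[1:] >= thr)
        idx = np.flatnonzero(hit) + 1
        if idx.size:
            keep = [idx[0]]
            min_gap = refractory * fs
            for i in idx[1:]:
                if i - keep[-1] >= min_gap:
                    keep.append(i)
            idx = np.array(keep)
        times.append(idx / fs)
    return CrossingEvents(times=times, thresholds=thresholds,
                          duration=raw.duration)


def select_active_channels(events: CrossingEvents,
                           duration: float | None = None,
                           min_rate: float = 1.0) -> np.ndarray:
    """Boolean mask of channels with >= ``min_rate`` crossings/s on average."""
    if duration is None:
        duration = events.duration
    if duration <= 0:
        raise ValueError("duration must be positive")
    rates = events.counts() / duration
    return rates >= min_rate


def compute_sbp(raw: WaveformBlock, band: tuple[float, float] = SBP_BAND,
                bin_width: float = 0.020, power: str = "abs") -> np.ndarray:
    """Spiking-band power binned in time; returns a T x N matrix.

    Band-pass to ``band``, take per-sample magnitude (``power="abs"``) or
    square (``power="mean_square"``), then average within each bin.  The
    trailing partial bin is dropped.
    """
    fs = raw.sampling_rate
    if fs <= 2 * band[1]:
        raise ValueError(
            f"sampling rate {fs} Hz must exceed twice the band top {band[1]} Hz")
    if power not in ("abs", "mean_square"):
        raise ValueError("power must be 'abs' or 'mean_square'")
    sos = _butter_sos(band, fs, "bandpass")
    x = sps.sosfiltfilt(sos, raw.samples, axis=1)
    x = np.abs(x) if power == "abs" else x ** 2
    samples_per_bin = int(round(bin_width * fs))
    n_bins = x.shape[1] // samples_per_bin
    x = x[:, :n_bins * samples_per_bin]
    binned = x.reshape(raw.n_channels, n_bins, samples_per_bin).mean(axis=2)
    return binned.T


def bin_waveform(raw: WaveformBlock, bin_width: float = 0.020) -> np.ndarray:
    """Average a waveform into fixed-width bins (T x channels)."""
    spb = int(round(bin_width * raw.sampling_rate))
    n_bins = raw.n_samples // spb
    x = raw.samples[:, :n_bins * spb]
    return x.reshape(raw.n_channels, n_bins, spb).mean(axis=2).T


def blank_artifact_windows(session: BinnedSession) -> BinnedSession:
    """Flag each trial's reward-pump artifact window in the session mask.

    Flagged bins are excluded from every downstream train/test index set;
    the data themselves are untouched (masked, not interpolated).
    """
    mask = np.zeros(session.n_bins, dtype=bool)
    tr = session.trials
    for i in range(len(tr)):
        a, b = tr.artifact_start[i], tr.artifact_end[i]
        if b > a:
            mask[a:min(b, session.n_bins)] = True
    if session.artifact_mask is not None:
        mask |= session.artifact_mask
    return session.replace(artifact_mask=mask)
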