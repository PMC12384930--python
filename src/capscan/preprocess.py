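"""EEG preprocessing: bandpass filtering, amplitude artifact rejection, baseline.

The pipeline mirrors standard CAP front-ends: a 0.25-40 Hz zero-phase
Butterworth bandpass, rejection of samples whose absolute amplitude exceeds
100 uV (with a +-0.5 s window around each offender), and a robust running
baseline amplitude against which Phase A activations are measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal


@dataclass
class EEGRecord:
    """Single-channel EEG: samples in microvolts at sampling rate ``fs`` Hz."""

    samples: np.ndarray
    fs: float
    channel: str = "EEG"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs


@dataclass
class CleanEEG:
    """Filtered EEG with a boolean artifact mask (True = rejected sample)."""

    samples: np.ndarray
    fs: float
    artifact_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    channel: str = "EEG"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.artifact_mask is None:
            self.artifact_mask = np.zeros(len(self.samples), dtype=bool)
        self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)


def bandpass_filter(record: EEGRecord, low_hz: float = 0.25, high_hz: float = 40.0) -> EEGRecord:
    """Zero-phase 4th-order Butterworth bandpass; same length and fs."""
    if not (0 < low_hz < high_hz < record.fs / 2):
        raise ValueError(
            f"invalid band ({low_hz}, {high_hz}) Hz for fs={record.fs} Hz"
        )
    sos = signal.butter(4, [low_hz, high_hz], btype="bandpass", fs=record.fs, output="sos")
    # the 0.25 Hz corner has multi-second transients; pad generously
    padlen = int(min(len(record.samples) - 1, 3 * record.fs / low_hz))
    filtered = signal.sosfiltfilt(sos, record.samples, padlen=padlen)
    return EEGRecord(samples=filtered, fs=record.fs, channel=record.channel)


def remove_artifacts(
    record: EEGRecord, threshold_uv: float = 100.0, rejection_window_s: float = 0.5
) -> CleanEEG:
    """Flag samples with |amplitude| > threshold, expanded by a rejection window.

    Flagged samples are masked out of downstream amplitude statistics rather
    than interpolated; the signal values themselves are left unchanged.
    """
    if threshold_uv <= 0:
        raise ValueError("threshold_uv must be positive")
    x = record.samples
    offenders = np.abs(x) > threshold_uv
    mask = offenders.copy()
    if offenders.any() and rejection_window_s > 0:
        half = int(round(rejection_window_s * record.fs))
        if half > 0:
            # dilate the offender mask by +-half samples
            kernel = np.ones(2 * half + 1)
            mask = np.convolve(offenders.astype(float), kernel, mode="same") > 0
    if mask.all():
        raise ValueError("every sample exceeds the artifact threshold; nothing analyzable")
    return CleanEEG(samples=x, fs=record.fs, artifact_mask=mask, channel=record.channel)


def envelope(clean: CleanEEG, smooth_s: float = 0.5) -> np.ndarray:
    """Smoothed analytic (Hilbert) amplitude envelope in microvolts.

    A short moving average suppresses the Rayleigh-like sample-to-sample
    envelope fluctuation of background EEG so that the 1.5x-baseline phase
    threshold operates on a sustained amplitude level, not instantaneous peaks.
    Masked (artifact) samples are zero-filled first: a large rejected spike
    would otherwise leak Hilbert tails into the envelope seconds away.
    """
    x = np.where(clean.artifact_mask, 0.0, clean.samples)
    env = np.abs(signal.hilbert(x))
    if smooth_s > 0:
        n = max(1, int(round(smooth_s * clean.fs)))
        kernel = np.ones(n) / n
        env = np.convolve(env, kernel, mode="same")
    return env


def baseline_amplitude(
    clean: CleanEEG, window_s: float = 60.0, step_s: float = 1.0
) -> np.ndarray:
    """Per-second robust baseline amplitude series (median smoothed envelope).

    A sliding window of ``window_s`` seconds, advanced every ``step_s``
    seconds, takes the median of the unmasked envelope: a robust scale so a
    Phase A burst cannot inflate its own reference.  Fully-masked windows
    carry the previous baseline forward.  Returns one value per step
    (length ceil(duration/step)).
    """
    if window_s < 2:
        raise ValueError("window_s must be >= 2 s")
    env = envelope(clean)
    fs = clean.fs
    n = len(env)
    n_steps = int(np.ceil(n / (step_s * fs)))
    half = int(round(window_s * fs / 2))
    out = np.empty(n_steps)
    prev = np.nan
    for k in range(n_steps):
        center = int(round((k + 0.5) * step_s * fs))
        lo, hi = max(0, center - half), min(n, center + half)
        win = env[lo:hi][~clean.artifact_mask[lo:hi]]
        if win.size == 0:
            if np.isnan(prev):
                raise ValueError("initial baseline window fully masked")
            out[k] = prev
        else:
            out[k] = float(np.median(win))
            prev = out[k]
    if (out <= 0).any():
        # degenerate all-zero window; keep positivity with a tiny floor
        out = np.maximum(out, np.finfo(float).tiny)
    return out


def baseline_per_sample(baseline: np.ndarray, n_samples: int, fs: float, step_s: float = 1.0) -> np.ndarray:
    """Expand a per-step baseline series to per-sample resolution."""
    idx = np.minimum((np.arange(n_samples) / (step_s * fs)).astype(int), len(baseline) - 1)
    return baseline[idx]
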