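"""Ground-truthed synthetic EEG: background noise, planted CAP bursts, annotations.

The generator emulates the phenomenology the detector is built for: 1/f-ish
band-limited background NREM EEG with a known baseline amplitude, and
amplitude-windowed Phase A bursts whose band composition satisfies a chosen
subtype rule with margin (A1 delta-dominant, A2 mixed, A3 alpha/beta).
Bursts are noise carriers, not sines, so wavelet band fractions, envelopes
and morphology are all nontrivial.  Planted events live only in NREM stage
segments; REM and wake segments stay event-free.

The planted ``amplitude_factor`` is calibrated against the *measured*
smoothed envelope: the burst is scaled so the sustained envelope plateau of
background+burst sits at ``amplitude_factor x baseline`` (the background adds
incoherently, so the raw burst scale is corrected downward).  That makes the
factor the detector thresholds on exactly the quantity the generator plants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .annotations import CANONICAL_COLUMNS, AnnotationTable
from .detect import CapEvent
from .preprocess import CleanEEG, EEGRecord, baseline_amplitude, baseline_per_sample, envelope

#: band-power weights each subtype's burst carrier mixes, with margin
#: relative to the classification thresholds (A1: delta 0.75 >= 0.60;
#: A2: delta 0.40 and theta+alpha 0.40, both inside [0.20, 0.60];
#: A3: alpha+beta 0.80 >= 0.60)
SUBTYPE_BAND_WEIGHTS: dict[str, dict[str, float]] = {
    "A1": {"delta": 0.85, "theta": 0.07, "alpha": 0.05, "beta": 0.03},
    "A2": {"delta": 0.45, "theta": 0.20, "alpha": 0.20, "beta": 0.15},
    "A3": {"delta": 0.05, "theta": 0.10, "alpha": 0.425, "beta": 0.425},
}

BAND_EDGES = {"delta": (0.5, 4.0), "theta": (4.0, 8.0), "alpha": (8.0, 13.0), "beta": (13.0, 30.0)}

#: burst amplitude ramp (seconds) — short so event edges stay crisp at the
#: 1-second timing granularity of CAP scoring
RAMP_S = 0.25


@dataclass
class SimConfig:
    fs: float = 128.0
    duration_s: float = 120.0
    baseline_amp_uv: float = 10.0
    events: list[tuple[float, float, str, float]] = field(default_factory=list)
    #: (label, start_s, duration_s) stage segments; default: all SLEEP-S2
    stage_blocks: list[tuple[str, float, float]] = field(default_factory=list)
    noise_level: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs < 64:
            raise ValueError("fs must be >= 64 Hz")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        last_end = -np.inf
        for onset, dur, subtype, factor in sorted(self.events):
            if subtype not in SUBTYPE_BAND_WEIGHTS:
                raise ValueError(f"unknown subtype {subtype!r}")
            if onset < last_end:
                raise ValueError("events overlap")
            if onset < 0 or onset + dur > self.duration_s:
                raise ValueError("event outside record")
            last_end = onset + dur


@dataclass
class GroundTruth:
    events: list[CapEvent]
    stage_track: list[str]  # one label per second
    annotation_table: AnnotationTable


def _bandlimited_noise(
    rng: np.random.Generator, n: int, fs: float, low: float, high: float, one_over_f: bool = False
) -> np.ndarray:
    """Gaussian noise confined to [low, high] Hz via FFT shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1 / fs)
    weight = ((freqs >= low) & (freqs <= high)).astype(float)
    if one_over_f:
        with np.errstate(divide="ignore"):
            weight = weight / np.sqrt(np.maximum(freqs, low))
        weight[~np.isfinite(weight)] = 0.0
    out = np.fft.irfft(spec * weight, n)
    rms = np.sqrt(np.mean(out**2))
    return out / rms if rms > 0 else out


def simulate_background(
    fs: float, duration_s: float, baseline_amp_uv: float = 10.0, seed: int = 0
) -> EEGRecord:
    """1/f-weighted 0.5-30 Hz noise scaled so the median smoothed envelope
    equals ``baseline_amp_uv``."""
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    x = _bandlimited_noise(rng, n, fs, 0.5, 30.0, one_over_f=True)
    env = envelope(CleanEEG(samples=x, fs=fs))
    x *= baseline_amp_uv / np.median(env)
    return EEGRecord(samples=x, fs=fs, channel="synthetic")


def _burst_window(n: int, fs: float) -> np.ndarray:
    """Flat-top window with cosine ramps of RAMP_S seconds on each side."""
    ramp = min(int(round(RAMP_S * fs)), n // 2)
    w = np.ones(n)
    if ramp > 0:
        up = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
        w[:ramp] = up
        w[-ramp:] = up[::-1]
    return w


def _subtype_carrier(rng: np.random.Generator, n: int, fs: float, subtype: str) -> np.ndarray:
    """Unit-envelope carrier whose band-energy shares follow the subtype mix.

    The carrier time-multiplexes unit-amplitude tones, one band at a time,
    in randomly interleaved slices whose total durations are allocated
    exactly in proportion to the subtype's band weights.  Each slice starts
    phase- and slope-matched to the previous one, so the waveform is
    continuous and its amplitude envelope is flat by construction — a sum of
    simultaneous band tones was rejected because adjacent bands beat at
    sub-hertz rates, rippling the envelope the detector thresholds on.
    """
    weights = SUBTYPE_BAND_WEIGHTS[subtype]
    slice_s = {"delta": 1.2, "theta": 0.8, "alpha": 0.6, "beta": 0.5}
    alloc = {b: int(round(w * n)) for b, w in weights.items()}
    # fix rounding drift on the largest allocation
    drift = n - sum(alloc.values())
    alloc[max(alloc, key=alloc.get)] += drift

    f_inst = np.empty(n)
    remaining = dict(alloc)
    pos = 0
    while pos < n:
        # band with the largest remaining allocation
        band = max(remaining, key=lambda b: remaining[b])
        if remaining[band] <= 0:
            break
        m = max(1, min(int(round(slice_s[band] * fs)), remaining[band], n - pos))
        lo, hi = BAND_EDGES[band]
        inset = 0.10 * (hi - lo)
        f_inst[pos : pos + m] = rng.uniform(lo + inset, hi - inset)
        remaining[band] -= m
        pos += m
    # smooth the frequency schedule: abrupt instantaneous-frequency jumps
    # leave transients in the analytic envelope at delta-band timescales
    k = max(1, int(round(0.3 * fs)))
    kernel = np.ones(k) / k
    f_smooth = np.convolve(np.pad(f_inst, (k // 2, k - 1 - k // 2), mode="edge"), kernel, mode="valid")
    phase = 2 * np.pi * np.cumsum(f_smooth) / fs + rng.uniform(0, 2 * np.pi)
    return np.cos(phase)


def inject_phase_a(
    record: EEGRecord,
    onset_s: float,
    duration_s: float,
    subtype: str,
    amplitude_factor: float,
    baseline_amp_uv: float,
    seed: int = 0,
    existing: list[CapEvent] | None = None,
) -> CapEvent:
    """Add a windowed subtype burst in place; returns the ground-truth event.

    The burst replaces the background under a crossfade window: on the
    plateau the signal is purely the subtype carrier at the target amplitude,
    so the sustained smoothed-envelope level equals ``amplitude_factor`` times
    the *locally measured* running baseline (median smoothed envelope over a
    60 s window around the burst — the same statistic the detector thresholds
    against).  Additive superposition was rejected because the delta-heavy
    background beats against delta-band carriers at near-zero frequencies,
    producing slow envelope ripple that no calibration can pin down.
    ``baseline_amp_uv`` is the nominal fallback when the record is too short
    to measure a local baseline.
    """
    for ev in existing or []:
        if onset_s < ev.end_s and onset_s + duration_s > ev.onset_s:
            raise ValueError("burst overlaps an existing event")
    fs = record.fs
    i0 = int(round(onset_s * fs))
    i1 = int(round((onset_s + duration_s) * fs))
    if i0 < 0 or i1 > len(record.samples):
        raise ValueError("burst outside record")
    rng = np.random.default_rng(seed)
    n = i1 - i0
    carrier = _subtype_carrier(rng, n, fs, subtype)
    window = _burst_window(n, fs)

    # initial plateau normalization: unit carrier's smoothed-envelope median
    ramp = int(round((RAMP_S + 0.5) * fs))
    if n > 2 * ramp + int(fs / 2):
        plateau_env = envelope(CleanEEG(samples=carrier, fs=fs))[ramp:-ramp]
        carrier = carrier / float(np.median(plateau_env))

    # calibrate the sustained plateau against the running baseline the
    # detector will actually measure on the modified record (the injected
    # burst itself nudges the local 60 s median, so iterate)
    half = int(round(35 * fs))
    lo, hi = max(0, i0 - half), min(len(record.samples), i1 + half)
    if hi - lo >= 8 * fs:
        bg_env = envelope(CleanEEG(samples=record.samples[lo:hi], fs=fs))
        target = amplitude_factor * float(np.median(bg_env))
    else:
        target = amplitude_factor * baseline_amp_uv
    original = record.samples[i0:i1].copy()
    for _ in range(2 if hi - lo >= 60 * fs and n > 2 * ramp + int(fs / 2) else 0):
        trial = record.samples[lo:hi].copy()
        trial[i0 - lo : i1 - lo] = (1 - window) * original + window * target * carrier
        chunk = CleanEEG(samples=trial, fs=fs)
        base = baseline_amplitude(chunk)
        bps = baseline_per_sample(base, hi - lo, fs)
        # the per-second baseline varies slightly across the event span; pin
        # against its maximum so the plateau clears the threshold throughout
        local_base = float(np.max(bps[i0 - lo + ramp : i1 - lo - ramp]))
        env_now = envelope(chunk)[i0 - lo + ramp : i1 - lo - ramp]
        # calibrate the low quantile: the *sustained* level sits at target,
        # sub-debounce dips notwithstanding
        plateau = float(np.quantile(env_now, 0.05))
        if plateau > 0:
            target *= amplitude_factor * local_base / plateau

    record.samples[i0:i1] = (1 - window) * original + window * target * carrier
    return CapEvent(
        phase="A",
        onset_s=onset_s,
        duration_s=duration_s,
        peak_amp_uv=target,
        band_fractions=dict(SUBTYPE_BAND_WEIGHTS[subtype]),
        subtype=subtype,
    )


def _default_stage_blocks(duration_s: float) -> list[tuple[str, float, float]]:
    return [("SLEEP-S2", 0.0, duration_s)]


def simulate_recording(config: SimConfig) -> tuple[EEGRecord, GroundTruth]:
    """Background plus all configured bursts, with stage track and annotations.

    Raises if an event is placed inside a REM or wake (S0) stage block —
    CAP activity is by definition an NREM phenomenon, and keeping those
    segments event-free is what lets stage-validation tests assert absence.
    """
    record = simulate_background(config.fs, config.duration_s, config.baseline_amp_uv, config.seed)
    blocks = config.stage_blocks or _default_stage_blocks(config.duration_s)

    stage_track: list[str] = []
    for sec in range(int(np.ceil(config.duration_s))):
        label = "SLEEP-S2"
        for name, start, dur in blocks:
            if start <= sec < start + dur:
                label = name
        stage_track.append(label)

    truth_events: list[CapEvent] = []
    for k, (onset, dur, subtype, factor) in enumerate(sorted(config.events)):
        stage = stage_track[min(int(onset), len(stage_track) - 1)]
        if stage in ("SLEEP-REM", "SLEEP-S0"):
            raise ValueError(f"event at {onset} s falls in non-CAP stage {stage}")
        ev = inject_phase_a(
            record,
            onset,
            dur,
            subtype,
            factor,
            config.baseline_amp_uv,
            seed=config.seed + 1000 + k,
            existing=truth_events,
        )
        truth_events.append(ev)

    if config.noise_level > 0:
        rng = np.random.default_rng(config.seed + 99)
        record.samples = record.samples + config.noise_level * config.baseline_amp_uv * rng.standard_normal(
            len(record.samples)
        )

    table = _annotation_from_track(stage_track, truth_events)
    return record, GroundTruth(events=truth_events, stage_track=stage_track, annotation_table=table)


def _annotation_from_track(stage_track: list[str], events: list[CapEvent]) -> AnnotationTable:
    """One row per second: Sleep Stage from the track, Event = MCAP label when
    a planted A phase covers that second, else the stage label."""
    rows = []
    for sec, stage in enumerate(stage_track):
        event_label = stage
        for ev in events:
            if ev.onset_s <= sec < ev.end_s:
                event_label = f"MCAP-{ev.subtype}"
                break
        hh, rem = divmod(sec, 3600)
        mm, ss = divmod(rem, 60)
        rows.append([stage, "N", f"{hh:02d}:{mm:02d}:{ss:02d}", event_label, 1.0, "C4-A1"])
    frame = pd.DataFrame(rows, columns=CANONICAL_COLUMNS)
    return AnnotationTable(frame=frame, patient_id="synthetic")


def simulate_feature_matrix(
    n_events: int = 500, n_features: int = 12, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Labeled synthetic event-feature matrix for the RF->PCA reduction.

    Three subtype classes with class-dependent means on four informative,
    mutually correlated columns; the rest is isotropic noise.  Mirrors the
    situation the reduction targets: a few correlated discriminative band
    features among generic ones.
    """
    if n_events < 10 or n_features < 5:
        raise ValueError("need >= 10 events and >= 5 features")
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, 3, size=n_events)
    centers = np.array(
        [
            [3.0, 0.5, 0.0, 1.0],
            [1.0, 2.0, 1.0, 0.0],
            [0.0, 0.5, 3.0, 2.0],
        ]
    )
    informative = centers[labels] + rng.standard_normal((n_events, 4))
    # correlate the informative block so PCA has structure to compress
    mix = np.array([[1.0, 0.4, 0.2, 0.1], [0.0, 1.0, 0.4, 0.2], [0.0, 0.0, 1.0, 0.4], [0.0, 0.0, 0.0, 1.0]])
    informative = informative @ mix
    noise = 0.5 * rng.standard_normal((n_events, n_features - 4))
    X = np.hstack([informative, noise])
    return X, labels
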