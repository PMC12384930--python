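"""Rule-based CAP phase detection, subtyping, sequencing and CAP-rate scoring.

A CAP cycle is an activation (Phase A, 2-60 s of EEG amplitude at or above
1.5x the running baseline) followed by a return to background (Phase B,
at least 2 s below that threshold).  Two or more consecutive A-B cycles form
a CAP sequence.  Phase A events are subtyped from their band-power fractions:
delta-dominant A1, mixed A2, alpha/beta-dominant A3.  The CAP rate —
the percentage of epochs that are not wake or REM — flags a recording as
pathological when it strictly exceeds 30%.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .features import band_powers_dwt
from .preprocess import CleanEEG, baseline_per_sample, envelope

#: default annotation labels that never count as CAP epochs
NON_CAP_LABELS = frozenset({"SLEEP-REM", "SLEEP-S0"})

SUBTYPE_STAGE_MAP = {"A1": "N3", "A2": "N1/N2", "A3": "N1/N2"}


@dataclass
class CapEvent:
    phase: str  # "A" or "B"
    onset_s: float
    duration_s: float
    peak_amp_uv: float = 0.0
    band_fractions: dict[str, float] | None = None
    subtype: str = "n/a"

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass
class CapSequence:
    cycles: list[tuple[CapEvent, CapEvent]]
    predominant_subtype: str = "Undefined"
    mapped_stage: str = "Unmapped"

    @property
    def onset_s(self) -> float:
        return self.cycles[0][0].onset_s

    @property
    def end_s(self) -> float:
        return self.cycles[-1][1].end_s

    @property
    def a_phases(self) -> list[CapEvent]:
        return [a for a, _ in self.cycles]


def classify_subtype(band_fractions: dict[str, float]) -> str:
    """Subtype an A phase from its band-power fractions.

    Rules applied in order: delta >= 60% -> A1; delta in [20%, 60%] and
    theta+alpha in [20%, 60%] -> A2; alpha+beta >= 60% -> A3; else Undefined.
    Boundaries are inclusive, so delta exactly 60% is A1, never A2.
    """
    d = band_fractions["delta"]
    t = band_fractions["theta"]
    a = band_fractions["alpha"]
    b = band_fractions["beta"]
    if d >= 0.60:
        return "A1"
    if 0.20 <= d <= 0.60 and 0.20 <= t + a <= 0.60:
        return "A2"
    if a + b >= 0.60:
        return "A3"
    return "Undefined"


def detect_phases(
    clean: CleanEEG,
    baseline: np.ndarray,
    amplitude_factor: float = 1.5,
    min_a_s: float = 2.0,
    max_a_s: float = 60.0,
    min_b_s: float = 2.0,
    debounce_s: float = 0.5,
) -> list[CapEvent]:
    """Scan the smoothed envelope for alternating Phase A / Phase B events.

    A maximal contiguous run with envelope >= ``amplitude_factor`` x baseline
    lasting ``min_a_s``..``max_a_s`` seconds becomes a Phase A (runs longer
    than ``max_a_s`` are truncated there); sub-``debounce_s`` dips inside a
    run do not terminate it.  The below-threshold stretch immediately
    following an A becomes a Phase B when it lasts at least ``min_b_s``.
    Events are non-overlapping and time-ordered; each A carries its peak
    envelope amplitude, DWT band fractions and subtype.
    """
    fs = clean.fs
    env = envelope(clean)
    base = baseline_per_sample(np.asarray(baseline, dtype=float), len(env), fs)
    above = (env >= amplitude_factor * base) & ~clean.artifact_mask

    runs = _runs(above)
    runs = _merge_runs(runs, max_gap=int(round(debounce_s * fs)))

    events: list[CapEvent] = []
    min_a = int(round(min_a_s * fs))
    max_a = int(round(max_a_s * fs))
    min_b = int(round(min_b_s * fs))
    n = len(env)
    # excursions too short to be an activation are background: they neither
    # become Phase A nor interrupt a Phase B stretch
    runs = [(start, stop) for start, stop in runs if stop - start >= min_a]
    quiet = _background_band_power(clean, above)
    for i, (start, stop) in enumerate(runs):
        a_stop = min(stop, start + max_a)
        seg = clean.samples[start:a_stop]
        fractions = _corrected_fractions(seg, fs, quiet)
        events.append(
            CapEvent(
                phase="A",
                onset_s=start / fs,
                duration_s=(a_stop - start) / fs,
                peak_amp_uv=float(env[start:a_stop].max()),
                band_fractions=fractions,
                subtype=classify_subtype(fractions),
            )
        )
        gap_start = stop
        gap_stop = runs[i + 1][0] if i + 1 < len(runs) else n
        if gap_stop - gap_start >= min_b:
            events.append(
                CapEvent(
                    phase="B",
                    onset_s=gap_start / fs,
                    duration_s=(gap_stop - gap_start) / fs,
                    peak_amp_uv=float(env[gap_start:gap_stop].max()) if gap_stop > gap_start else 0.0,
                )
            )
    return events


def _background_band_power(clean: CleanEEG, above: np.ndarray) -> np.ndarray | None:
    """Quiescent background samples for reference band-power estimation.

    Returns the longest below-threshold, artifact-free stretch (>= 4 s), or
    None.  Phase A segments contain background activity underneath the burst;
    subtracting a background reference exposes the activation's own band
    composition, which is what the subtype rules describe.
    """
    quiet = ~above & ~clean.artifact_mask
    best = max(_runs(quiet), key=lambda r: r[1] - r[0], default=None)
    if best is None or best[1] - best[0] < 4 * clean.fs:
        return None
    return clean.samples[best[0] : best[1]]


def _corrected_fractions(
    segment: np.ndarray, fs: float, quiet: np.ndarray | None
) -> dict[str, float]:
    powers, fractions = band_powers_dwt(segment, fs)
    if quiet is None:
        return fractions
    # reference estimated on a same-length quiet chunk so both estimates use
    # the same wavelet depth (the packet level depends on segment length)
    n = len(segment)
    if len(quiet) >= n:
        mid = (len(quiet) - n) // 2
        ref_seg = quiet[mid : mid + n]
    else:
        reps = int(np.ceil(n / len(quiet)))
        ref_seg = np.tile(quiet, reps)[:n]
    ref_powers, _ = band_powers_dwt(ref_seg, fs)
    corrected = {b: max(powers[b] - ref_powers[b], 0.0) for b in powers}
    total = sum(corrected.values())
    if total <= 0:
        return fractions
    return {b: p / total for b, p in corrected.items()}


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs of True."""
    padded = np.diff(np.concatenate(([0], mask.astype(int), [0])))
    starts = np.flatnonzero(padded == 1)
    stops = np.flatnonzero(padded == -1)
    return list(zip(starts.tolist(), stops.tolist()))


def _merge_runs(runs: list[tuple[int, int]], max_gap: int) -> list[tuple[int, int]]:
    if not runs:
        return []
    merged = [runs[0]]
    for start, stop in runs[1:]:
        if start - merged[-1][1] < max_gap:
            merged[-1] = (merged[-1][0], stop)
        else:
            merged.append((start, stop))
    return merged


def assemble_sequences(events: list[CapEvent], min_cycles: int = 2) -> list[CapSequence]:
    """Group alternating A-B events into valid CAP sequences.

    Maximal alternating runs starting at an A are paired into cycles; a
    trailing unpaired A is dropped; runs with fewer than ``min_cycles``
    complete cycles are discarded.  The predominant subtype is the modal
    subtype among the sequence's A phases (Undefined phases count toward
    validity but not the vote; ties resolve to the earlier-occurring subtype).
    """
    sequences: list[CapSequence] = []
    i = 0
    while i < len(events):
        if events[i].phase != "A":
            i += 1
            continue
        cycles: list[tuple[CapEvent, CapEvent]] = []
        j = i
        while j + 1 < len(events) and events[j].phase == "A" and events[j + 1].phase == "B":
            cycles.append((events[j], events[j + 1]))
            j += 2
        if len(cycles) >= min_cycles:
            seq = CapSequence(cycles=cycles)
            seq.predominant_subtype = _predominant_subtype(seq.a_phases)
            seq.mapped_stage = map_to_sleep_stage(seq)
            sequences.append(seq)
        i = max(j, i + 1)
    return sequences


def _predominant_subtype(a_phases: list[CapEvent]) -> str:
    votes = [a.subtype for a in a_phases if a.subtype in ("A1", "A2", "A3")]
    if not votes:
        return "Undefined"
    counts: dict[str, int] = {}
    for s in votes:
        counts[s] = counts.get(s, 0) + 1
    best = max(counts.values())
    # tie -> earliest-occurring subtype
    for s in votes:
        if counts[s] == best:
            return s
    return "Undefined"


def map_to_sleep_stage(seq: CapSequence) -> str:
    """A1-predominant sequences map to deep sleep N3; A2/A3 to light N1/N2."""
    return SUBTYPE_STAGE_MAP.get(seq.predominant_subtype, "Unmapped")


def cap_rate(
    epoch_labels: list[str],
    non_cap_labels: frozenset[str] | set[str] = NON_CAP_LABELS,
    pathology_threshold_pct: float = 30.0,
) -> tuple[float, bool]:
    """CAP rate in percent and the pathology flag.

    rate = 100 * (total - #labels in ``non_cap_labels``) / total; the
    recording is flagged pathological when the rate strictly exceeds the
    clinical 30% threshold.
    """
    if len(epoch_labels) == 0:
        raise ValueError("empty epoch label list")
    total = len(epoch_labels)
    non_cap = sum(1 for lab in epoch_labels if lab in non_cap_labels)
    rate = 100.0 * (total - non_cap) / total
    return rate, rate > pathology_threshold_pct


def events_to_jsonl(events: list[CapEvent]) -> str:
    lines = []
    for e in events:
        lines.append(
            json.dumps(
                {
                    "phase": e.phase,
                    "onset_s": e.onset_s,
                    "end_s": e.end_s,
                    "duration_s": e.duration_s,
                    "peak_amp_uv": e.peak_amp_uv,
                    "band_fractions": e.band_fractions,
                    "subtype": e.subtype,
                }
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")


def events_to_bed(events: list[CapEvent]) -> str:
    """BED-like tab table: onset_s, end_s, phase, subtype."""
    rows = [f"{e.onset_s:.3f}\t{e.end_s:.3f}\t{e.phase}\t{e.subtype}" for e in events]
    return "\n".join(rows) + ("\n" if rows else "")
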