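"""CAP phase detection, subtype rules, sequence assembly and CAP rate."""

import itertools

import numpy as np
import pytest

from capscan.detect import (
    CapEvent,
    assemble_sequences,
    cap_rate,
    classify_subtype,
    detect_phases,
    map_to_sleep_stage,
)
from capscan.preprocess import CleanEEG, baseline_amplitude
from capscan.synthetic import inject_phase_a, simulate_background


def _detect(record):
    clean = CleanEEG(samples=record.samples, fs=record.fs)
    base = baseline_amplitude(clean)
    return detect_phases(clean, base)


def _oracle_subtype(d, t, a, b):
    """Independent rule-table transcription of the printed thresholds."""
    if d >= 0.60:
        return "A1"
    if 0.20 <= d <= 0.60 and 0.20 <= t + a <= 0.60:
        return "A2"
    if a + b >= 0.60:
        return "A3"
    return "Undefined"


class TestClassifySubtype:
    @pytest.mark.parametrize(
        "fractions, expected",
        [
            ({"delta": 0.70, "theta": 0.10, "alpha": 0.10, "beta": 0.10}, "A1"),
            ({"delta": 0.40, "theta": 0.20, "alpha": 0.20, "beta": 0.20}, "A2"),
            ({"delta": 0.10, "theta": 0.10, "alpha": 0.40, "beta": 0.40}, "A3"),
            ({"delta": 0.60, "theta": 0.20, "alpha": 0.10, "beta": 0.10}, "A1"),  # boundary -> A1
            ({"delta": 0.05, "theta": 0.50, "alpha": 0.05, "beta": 0.40}, "Undefined"),
        ],
    )
    def test_printed_examples(self, fractions, expected):
        assert classify_subtype(fractions) == expected

    def test_full_simplex_grid_matches_oracle(self):
        step = 0.05
        grid = np.arange(0, 1.0 + 1e-9, step)
        for d, t, a in itertools.product(grid, repeat=3):
            b = 1.0 - d - t - a
            if b < -1e-9:
                continue
            b = max(b, 0.0)
            fr = {"delta": d, "theta": t, "alpha": a, "beta": b}
            assert classify_subtype(fr) == _oracle_subtype(d, t, a, b)


class TestDetectPhases:
    def test_background_only_gives_no_events(self):
        rec = simulate_background(128, 120, 10.0, seed=0)
        a_events = [e for e in _detect(rec) if e.phase == "A"]
        assert a_events == []

    def test_single_burst_gives_one_a_and_one_b(self):
        rec = simulate_background(128, 120, 10.0, seed=1)
        inject_phase_a(rec, 40.0, 5.0, "A1", 2.0, 10.0, seed=2)
        events = _detect(rec)
        a = [e for e in events if e.phase == "A"]
        b = [e for e in events if e.phase == "B"]
        assert len(a) == 1 and len(b) >= 1
        assert abs(a[0].onset_s - 40.0) < 1.0
        assert abs(a[0].duration_s - 5.0) < 0.5

    def test_one_second_burst_rejected(self):
        rec = simulate_background(128, 120, 10.0, seed=3)
        inject_phase_a(rec, 40.0, 1.0, "A1", 3.0, 10.0, seed=4)
        a = [e for e in _detect(rec) if e.phase == "A" and abs(e.onset_s - 40) < 3]
        assert a == []

    def test_events_disjoint_and_ordered(self):
        rec = simulate_background(128, 180, 10.0, seed=5)
        for k, onset in enumerate([20, 45, 70, 95, 120]):
            inject_phase_a(rec, float(onset), 4.0, "A3", 2.2, 10.0, seed=10 + k)
        events = _detect(rec)
        for e1, e2 in zip(events, events[1:]):
            assert e1.end_s <= e2.onset_s + 1e-9

    def test_band_fractions_normalized(self):
        rec = simulate_background(128, 120, 10.0, seed=6)
        inject_phase_a(rec, 40.0, 5.0, "A2", 2.2, 10.0, seed=7)
        a = [e for e in _detect(rec) if e.phase == "A"][0]
        assert abs(sum(a.band_fractions.values()) - 1.0) < 1e-9


def _ev(phase, onset, dur, subtype="n/a"):
    return CapEvent(phase=phase, onset_s=onset, duration_s=dur, subtype=subtype)


class TestSequences:
    def test_two_cycles_form_one_sequence(self):
        events = [_ev("A", 0, 5, "A1"), _ev("B", 5, 10), _ev("A", 15, 5, "A1"), _ev("B", 20, 10)]
        seqs = assemble_sequences(events)
        assert len(seqs) == 1 and len(seqs[0].cycles) == 2

    def test_single_cycle_is_invalid(self):
        seqs = assemble_sequences([_ev("A", 0, 5, "A1"), _ev("B", 5, 10)])
        assert seqs == []

    def test_trailing_unpaired_a_dropped(self):
        events = [
            _ev("A", 0, 5, "A1"),
            _ev("B", 5, 10),
            _ev("A", 15, 5, "A2"),
            _ev("B", 20, 10),
            _ev("A", 30, 5, "A3"),
        ]
        seqs = assemble_sequences(events)
        assert len(seqs) == 1 and len(seqs[0].cycles) == 2

    def test_predominant_subtype_tie_goes_to_earlier(self):
        events = [
            _ev("A", 0, 5, "A2"),
            _ev("B", 5, 5),
            _ev("A", 10, 5, "A1"),
            _ev("B", 15, 5),
        ]
        assert assemble_sequences(events)[0].predominant_subtype == "A2"

    def test_undefined_counts_for_validity_not_vote(self):
        events = [
            _ev("A", 0, 5, "Undefined"),
            _ev("B", 5, 5),
            _ev("A", 10, 5, "A3"),
            _ev("B", 15, 5),
        ]
        seq = assemble_sequences(events)[0]
        assert seq.predominant_subtype == "A3"

    @pytest.mark.parametrize(
        "subtype, stage", [("A1", "N3"), ("A2", "N1/N2"), ("A3", "N1/N2"), ("Undefined", "Unmapped")]
    )
    def test_stage_mapping(self, subtype, stage):
        events = [_ev("A", 0, 5, subtype), _ev("B", 5, 5), _ev("A", 10, 5, subtype), _ev("B", 15, 5)]
        assert map_to_sleep_stage(assemble_sequences(events)[0]) == stage


class TestCapRate:
    def test_reported_worked_example(self):
        labels = ["SLEEP-REM"] * 2335 + ["SLEEP-S0"] * 2141 + ["OTHER"] * (19590 - 4476)
        rate, pathological = cap_rate(labels)
        assert round(rate, 2) == 77.15
        assert pathological

    def test_all_rem_rate_zero(self):
        rate, pathological = cap_rate(["SLEEP-REM"] * 50)
        assert rate == 0.0 and not pathological

    def test_exactly_thirty_percent_not_pathological(self):
        labels = ["CAP"] * 30 + ["SLEEP-REM"] * 70
        rate, pathological = cap_rate(labels)
        assert rate == 30.0 and not pathological

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            cap_rate([])
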