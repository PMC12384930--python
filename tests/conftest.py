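"""Shared fixtures and synthetic-data helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from capscan.annotations import CANONICAL_COLUMNS, AnnotationTable
from capscan.dataset import SequenceDataset

STAGES = ["SLEEP-S0", "SLEEP-S2", "SLEEP-S3", "SLEEP-REM"]
EVENTS = ["MCAP-A1", "MCAP-A2", "MCAP-A3", "SLEEP-S2"]


def random_annotation_table(rng: np.random.Generator, n_rows: int = 8, patient_id: str = "p") -> AnnotationTable:
    rows = []
    for i in range(n_rows):
        sec = int(rng.integers(0, 86_000))
        hh, rem = divmod(sec, 3600)
        mm, ss = divmod(rem, 60)
        rows.append(
            [
                STAGES[rng.integers(len(STAGES))],
                ["N", "Left", "Right"][rng.integers(3)],
                f"{hh:02d}:{mm:02d}:{ss:02d}",
                EVENTS[rng.integers(len(EVENTS))],
                float(np.round(rng.uniform(0.5, 60.0), 3)),
                ["C4-A1", "F4-C4"][rng.integers(2)],
            ]
        )
    return AnnotationTable(frame=pd.DataFrame(rows, columns=CANONICAL_COLUMNS), patient_id=patient_id)


def separable_sequences(
    n_seq: int = 40, steps: int = 10, n_feat: int = 4, seed: int = 0
) -> SequenceDataset:
    """Two-class per-step sequences separable by a linear rule."""
    rng = np.random.default_rng(seed)
    y = (rng.random((n_seq, steps)) < 0.5).astype(int)
    centers = np.array([[1.0, 0.0, 0.5, -0.5], [-1.0, 1.0, -0.5, 0.5]])[:, :n_feat]
    X = centers[y] + 0.1 * rng.standard_normal((n_seq, steps, n_feat))
    return SequenceDataset(
        inputs=X,
        targets=y,
        pad_mask=np.zeros((n_seq, steps), dtype=bool),
        class_names=["background", "activation"],
        feature_names=[f"f{i}" for i in range(n_feat)],
    )


def imbalanced_sequences(
    n_seq: int = 60, steps: int = 10, seed: int = 0, p_minority: float = 0.1, separation: float = 0.8
) -> SequenceDataset:
    """9:1 imbalanced, partially overlapping two-class sequences."""
    rng = np.random.default_rng(seed)
    y = (rng.random((n_seq, steps)) < p_minority).astype(int)
    centers = np.array([[0.0, 0.0, 0.0, 0.0], [separation, separation, 0.0, 0.0]])
    X = centers[y] + 0.6 * rng.standard_normal((n_seq, steps, 4))
    return SequenceDataset(
        inputs=X,
        targets=y,
        pad_mask=np.zeros((n_seq, steps), dtype=bool),
        class_names=["majority", "minority"],
        feature_names=["f0", "f1", "f2", "f3"],
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def toy_annotation_text() -> str:
    return (
        "CAP Sleep Database style export\n"
        "Sleep Stage\tPosition\tTime [hh:mm:ss]\tEvent\tDuration[s]\tLocation\n"
        "SLEEP-S2\tN\t00:00:01\tMCAP-A1\t5.0\tC4-A1\n"
        "SLEEP-S2\tN\t00:00:06\tMCAP-A2\t\tC4-A1\n"
        "SLEEP-REM\tN\t00:00:11\tSLEEP-REM\t30\tC4-A1\n"
    )
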