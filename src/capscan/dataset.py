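"""Fixed-length per-timestep training sequences and inverse-frequency weights.

Encoded annotation rows become non-overlapping windows of ten time steps
(the classifier predicts a class at every step, not one per sequence).
Windows never straddle patients; the final partial window is zero-padded
with a mask so padded steps stay out of the loss and the metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_STEPS = 10

#: per-step input feature order (metadata features; optional F1..Fk appended)
METADATA_FEATURES = ["Sleep Stage", "Position", "Location", "Duration[s]"]


@dataclass
class SequenceDataset:
    inputs: np.ndarray  # n_sequences x steps x n_features
    targets: np.ndarray  # n_sequences x steps int codes
    pad_mask: np.ndarray  # n_sequences x steps, True = padded
    class_names: list[str]
    feature_names: list[str] = field(default_factory=list)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @property
    def steps(self) -> int:
        return self.inputs.shape[1]


@dataclass
class ClassWeights:
    weights: np.ndarray  # one positive weight per class
    class_names: list[str]

    def as_dict(self) -> dict[str, float]:
        return {c: float(w) for c, w in zip(self.class_names, self.weights)}


def build_sequences(
    encoded_rows: pd.DataFrame | dict[str, pd.DataFrame],
    steps: int = DEFAULT_STEPS,
    feature_columns: list[str] | None = None,
    target_column: str = "Event",
    class_names: list[str] | None = None,
) -> SequenceDataset:
    """Window encoded rows into [n_sequences x steps x n_features] + targets.

    ``encoded_rows`` is either one patient's time-ordered frame or a
    mapping patient_id -> frame; windows are built per patient so no
    sequence mixes patients.  Per-step target = the row's Event label code
    (codes follow sorted unique labels over all rows unless ``class_names``
    pins the order).
    """
    if isinstance(encoded_rows, pd.DataFrame):
        frames = {"": encoded_rows}
    else:
        frames = dict(encoded_rows)
    total_rows = sum(len(f) for f in frames.values())
    if total_rows == 0:
        raise ValueError("zero rows; nothing to window")

    feats = feature_columns or [c for c in METADATA_FEATURES if c in next(iter(frames.values())).columns]
    if class_names is None:
        labels: set[str] = set()
        for f in frames.values():
            labels.update(str(v) for v in f[target_column])
        class_names = sorted(labels)
    code = {c: i for i, c in enumerate(class_names)}

    xs, ys, masks = [], [], []
    for pid in sorted(frames):
        frame = frames[pid]
        X = frame[feats].to_numpy(dtype=float)
        y = np.array([code[str(v)] for v in frame[target_column]], dtype=int)
        for start in range(0, len(frame), steps):
            xw = X[start : start + steps]
            yw = y[start : start + steps]
            pad = steps - len(xw)
            mask = np.zeros(steps, dtype=bool)
            if pad > 0:
                xw = np.vstack([xw, np.zeros((pad, X.shape[1]))])
                yw = np.concatenate([yw, np.zeros(pad, dtype=int)])
                mask[steps - pad :] = True
            xs.append(xw)
            ys.append(yw)
            masks.append(mask)
    return SequenceDataset(
        inputs=np.stack(xs),
        targets=np.stack(ys),
        pad_mask=np.stack(masks),
        class_names=list(class_names),
        feature_names=list(feats),
    )


def class_weights(counts: dict[str, int] | None = None, dataset: SequenceDataset | None = None) -> ClassWeights:
    """Inverse-frequency weights w_c = N_total / (K * n_c).

    With these weights, w_c * n_c is constant across classes and sums to
    N_total, so a uniformly wrong predictor pays the same weighted loss
    regardless of how imbalanced the label counts are.
    """
    if counts is None:
        if dataset is None:
            raise ValueError("provide counts or a dataset")
        observed = dataset.targets[~dataset.pad_mask]
        counts = {
            name: int(np.sum(observed == i)) for i, name in enumerate(dataset.class_names)
        }
    names = list(counts)
    n = np.array([counts[c] for c in names], dtype=float)
    if (n <= 0).any():
        zero = [c for c, v in counts.items() if v <= 0]
        raise ValueError(f"zero-count class(es): {zero}")
    total, k = n.sum(), len(n)
    return ClassWeights(weights=total / (k * n), class_names=names)
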