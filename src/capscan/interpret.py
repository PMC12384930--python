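"""Post hoc attribution for the sequence classifier, SHAP-style aggregations.

The deterministic occlusion method scores each input cell (time step s,
feature f) by how much the predicted probability of the sample's top class
drops when that cell is replaced by the background mean.  Three aggregation
views summarize a batch of attributions: mean |value| per time step, per
feature, and the full time x feature heatmap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class AttributionTensor:
    values: np.ndarray  # n_samples x steps x n_features, signed
    method: str
    baseline_spec: str

    def __post_init__(self) -> None:
        if not np.isfinite(self.values).all():
            raise ValueError("attributions must be finite")


def attribute(
    model,
    samples: np.ndarray,
    background: np.ndarray,
    method: str = "occlusion",
    seed: int = 0,
) -> AttributionTensor:
    """Per-cell contributions to each sample's top predicted class.

    Occlusion: attribution(i, s, f) = p_top(x_i) - p_top(x_i with cell
    (s, f) set to the background mean).  A feature the model ignores gets
    (exactly) zero attribution; for a linear single-step model the value is
    proportional to coefficient x (x - baseline).
    """
    if method != "occlusion":
        raise ValueError(f"unknown attribution method {method!r}")
    samples = np.asarray(samples, dtype=float)
    background = np.asarray(background, dtype=float)
    if background.size == 0:
        raise ValueError("background set is empty")
    base = background.mean(axis=0)  # steps x features

    probs = model.predict_proba(samples)  # n x steps x K
    top = probs.mean(axis=1).argmax(axis=1)  # per-sample top class
    p_ref = probs.mean(axis=1)[np.arange(len(samples)), top]

    n, steps, n_feat = samples.shape
    values = np.zeros((n, steps, n_feat))
    for s in range(steps):
        for f in range(n_feat):
            occluded = samples.copy()
            occluded[:, s, f] = base[s, f]
            p_occ = model.predict_proba(occluded).mean(axis=1)[np.arange(n), top]
            values[:, s, f] = p_ref - p_occ
    return AttributionTensor(
        values=values,
        method="occlusion",
        baseline_spec=f"mean of {len(background)} background samples",
    )


def aggregate_attributions(
    attr: AttributionTensor,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(per_step, per_feature, heatmap) means of |attribution|.

    per_step averages |values| over samples and features; per_feature over
    samples and steps; the heatmap over samples only.  Consequently the mean
    of per_step equals the mean of per_feature equals the grand mean.
    """
    a = np.abs(attr.values)
    per_step = a.mean(axis=(0, 2))
    per_feature = a.mean(axis=(0, 1))
    heatmap = a.mean(axis=0)
    return per_step, per_feature, heatmap
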