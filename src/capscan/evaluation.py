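"""Classification metrics and statistical validation for CAP scoring.

Beyond the usual confusion matrix and per-class precision/recall/F1, this
module carries the statistics the validation battery needs: one-vs-rest
ROC AUC from midrank placements, stratified percentile bootstrap confidence
intervals, DeLong's paired test for correlated AUCs, and Cohen's kappa with
the clinical reliability rule (kappa >= 0.85 -> "High", else
"Review needed").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import stats
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

KAPPA_HIGH_THRESHOLD = 0.85


@dataclass
class EvalReport:
    confusion: np.ndarray  # K x K counts, rows = true
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray
    accuracy: float
    auc: np.ndarray | None = None
    auc_ci: list[tuple[float, float]] | None = None
    kappa: float | None = None
    reliability: str | None = None

    @property
    def macro_auc(self) -> float | None:
        return None if self.auc is None else float(np.mean(self.auc))


def classification_report(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int) -> EvalReport:
    """Confusion matrix and per-class precision/recall/F1 (0/0 counts as 0)."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    labels = np.arange(n_classes)
    cm = confusion_matrix(y_true, y_pred, labels=labels)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p, r, f, s = precision_recall_fscore_support(
            y_true, y_pred, labels=labels, zero_division=0
        )
    return EvalReport(
        confusion=cm,
        precision=p,
        recall=r,
        f1=f,
        support=s,
        accuracy=float(np.mean(y_true == y_pred)),
    )


def _auc_rank(y: np.ndarray, scores: np.ndarray) -> float:
    """Mann-Whitney AUC with midrank tie handling."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("AUC needs both classes present")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    return float((ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2) / (len(pos) * len(neg)))


def roc_auc_ovr(y_true: np.ndarray, probs: np.ndarray) -> np.ndarray:
    """Per-class one-vs-rest AUC from the rank statistic."""
    y_true = np.asarray(y_true, dtype=int)
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 2:
        raise ValueError("probs must be [n x K]")
    return np.array([_auc_rank((y_true == k).astype(int), probs[:, k]) for k in range(probs.shape[1])])


def bootstrap_ci(
    metric: Callable[[np.ndarray, np.ndarray], float],
    y_true: np.ndarray,
    scores: np.ndarray,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Stratified percentile bootstrap interval for ``metric(y, scores)``.

    Resampling is stratified by class so no resample loses a class entirely
    (which would leave AUC-like metrics undefined).
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    y_true = np.asarray(y_true)
    scores = np.asarray(scores)
    rng = np.random.default_rng(seed)
    strata = [np.flatnonzero(y_true == c) for c in np.unique(y_true)]
    vals = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate([rng.choice(s, size=len(s), replace=True) for s in strata])
        vals[b] = metric(y_true[idx], scores[idx])
    alpha = (1 - level) / 2
    return float(np.quantile(vals, alpha)), float(np.quantile(vals, 1 - alpha))


def _delong_placements(y: np.ndarray, scores: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus per-observation structural components (V10, V01)."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = len(pos), len(neg)
    all_scores = np.concatenate([pos, neg])
    ranks = stats.rankdata(all_scores)
    ranks_pos = stats.rankdata(pos)
    ranks_neg = stats.rankdata(neg)
    v10 = (ranks[:m] - ranks_pos) / n
    v01 = 1.0 - (ranks[m:] - ranks_neg) / m
    auc = float(v10.mean())
    return auc, v10, v01


def delong_test(
    y_true: np.ndarray, scores_a: np.ndarray, scores_b: np.ndarray
) -> tuple[float, float, float, float]:
    """DeLong's paired test for two correlated AUCs on the same labels.

    Returns (auc_a, auc_b, z, p) with a two-sided normal p-value; identical
    scores (zero variance of the difference) give z = 0 and p = 1 by
    convention.  Note the underlying theory assumes the two score vectors
    are paired on the *same* binary labels; comparing AUCs of different
    classes breaks that pairing and the p-value is then only heuristic.
    """
    y = np.asarray(y_true, dtype=int)
    if len(np.unique(y)) != 2:
        raise ValueError("y_true must contain exactly two classes")
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    auc_a, v10_a, v01_a = _delong_placements(y, a)
    auc_b, v10_b, v01_b = _delong_placements(y, b)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.stack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var_diff <= 0:
        return auc_a, auc_b, 0.0, 1.0
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    p = float(2 * stats.norm.sf(abs(z)))
    return auc_a, auc_b, float(z), p


def cohen_kappa_reliability(y1: np.ndarray, y2: np.ndarray) -> tuple[float, str]:
    """Chance-corrected agreement and the reliability label.

    kappa = (p_o - p_e) / (1 - p_e); agreement is rated "High" when
    kappa >= 0.85, otherwise "Review needed".
    """
    y1 = np.asarray(y1)
    y2 = np.asarray(y2)
    if y1.shape != y2.shape:
        raise ValueError("label vectors must have equal length")
    labels = np.unique(np.concatenate([y1, y2]))
    n = len(y1)
    p_o = float(np.mean(y1 == y2))
    p_e = float(sum(np.mean(y1 == c) * np.mean(y2 == c) for c in labels))
    kappa = 1.0 if p_e == 1.0 else (p_o - p_e) / (1 - p_e)
    label = "High" if kappa >= KAPPA_HIGH_THRESHOLD else "Review needed"
    return kappa, label


def evaluate(
    y_true: np.ndarray,
    probs: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    reference: np.ndarray | None = None,
) -> EvalReport:
    """Full report: confusion, PRF, per-class OvR AUC with bootstrap CIs,
    and kappa against ``reference`` labels (default: the true labels,
    measuring scorer-vs-model agreement)."""
    y_true = np.asarray(y_true, dtype=int)
    probs = np.asarray(probs, dtype=float)
    y_pred = probs.argmax(axis=1)
    report = classification_report(y_true, y_pred, probs.shape[1])
    report.auc = roc_auc_ovr(y_true, probs)
    cis = []
    for k in range(probs.shape[1]):
        yk = (y_true == k).astype(int)
        if len(np.unique(yk)) < 2:
            cis.append((float("nan"), float("nan")))
            continue
        cis.append(
            bootstrap_ci(
                lambda yy, ss: _auc_rank(yy, ss), yk, probs[:, k], n_boot=n_boot, seed=seed + k
            )
        )
    report.auc_ci = cis
    ref = y_true if reference is None else np.asarray(reference, dtype=int)
    report.kappa, report.reliability = cohen_kappa_reliability(ref, y_pred)
    return report
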