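"""End-to-end pipeline on a synthetic recording: simulate -> detect ->
features -> dataset -> train -> evaluate -> interpret -> CAP rate.

Every stage seeds its randomness from the global seed via stage-name
hashing, so two runs with the same config produce identical artifacts.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from . import detect as detect_mod
from . import synthetic
from .annotations import encode_labels
from .config import RunConfig
from .dataset import build_sequences, class_weights
from .evaluation import evaluate
from .features import FEATURE_NAMES, extract_event_features, rf_pca_reduce
from .interpret import aggregate_attributions, attribute
from .nn import HyperParams, build_model, train_model
from .preprocess import CleanEEG, EEGRecord, bandpass_filter, baseline_amplitude, remove_artifacts

log = logging.getLogger("capscan")


def default_stage_blocks(duration_s: float) -> list[tuple[str, float, float]]:
    """A miniature hypnogram slice: NREM (S2, S3), then REM, then wake."""
    d = duration_s
    return [
        ("SLEEP-S2", 0.0, 0.4 * d),
        ("SLEEP-S3", 0.4 * d, 0.2 * d),
        ("SLEEP-REM", 0.6 * d, 0.25 * d),
        ("SLEEP-S0", 0.85 * d, 0.15 * d),
    ]


def default_event_plan(duration_s: float, seed: int) -> list[tuple[float, float, str, float]]:
    """A plausible planted-event plan: bursts of each subtype, 4-8 s long,
    1.8-2.5x baseline, >= 6 s of quiescence apart, NREM segments only."""
    rng = np.random.default_rng(seed)
    nrem_end = 0.6 * duration_s  # matches default_stage_blocks
    events = []
    t = 10.0
    subtypes = ["A1", "A2", "A3"]
    k = 0
    while t + 10 < nrem_end - 5:
        dur = float(rng.uniform(4, 8))
        factor = float(rng.uniform(1.8, 2.5))
        events.append((t, dur, subtypes[k % 3], factor))
        k += 1
        t += dur + float(rng.uniform(6, 12))
    return events


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Run every stage on a synthetic recording; artifacts under ``out_dir``.

    Returns the report dictionary that is also written to report.json.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)

    # --- simulate ---------------------------------------------------------
    sim_seed = config.stage_seed("simulate")
    events = default_event_plan(config.simulate.duration_s, sim_seed)
    sim = synthetic.SimConfig(
        fs=config.simulate.fs,
        duration_s=config.simulate.duration_s,
        baseline_amp_uv=config.simulate.baseline_amp_uv,
        events=events,
        stage_blocks=default_stage_blocks(config.simulate.duration_s),
        noise_level=config.simulate.noise_level,
        seed=sim_seed,
    )
    record, truth = synthetic.simulate_recording(sim)
    log.info("simulate: %d planted events, %.0f s", len(truth.events), record.duration_s)

    # --- preprocess + detect ---------------------------------------------
    filtered = bandpass_filter(record, config.filter.low_hz, config.filter.high_hz)
    clean = remove_artifacts(
        filtered, config.artifact.threshold_uv, config.artifact.rejection_window_s
    )
    baseline = baseline_amplitude(clean, config.baseline.window_s)
    detected = detect_mod.detect_phases(
        clean,
        baseline,
        amplitude_factor=config.detect.amplitude_factor,
        min_a_s=config.detect.min_a_s,
        max_a_s=config.detect.max_a_s,
        min_b_s=config.detect.min_b_s,
    )
    sequences = detect_mod.assemble_sequences(detected, min_cycles=config.detect.min_cycles)
    (out / "events.jsonl").write_text(detect_mod.events_to_jsonl(detected))
    (out / "events.bed").write_text(detect_mod.events_to_bed(detected))
    log.info("detect: %d events, %d sequences", len(detected), len(sequences))

    # --- per-row signal features (F1..Fk) ---------------------------------
    table = truth.annotation_table
    encoded, _enc = encode_labels(table)
    feat_rows = []
    half_win = 2.0  # seconds of signal context per annotation row
    n_samp = len(clean.samples)
    for sec in range(len(encoded)):
        c = int((sec + 0.5) * record.fs)
        lo = max(0, c - int(half_win * record.fs))
        hi = min(n_samp, c + int(half_win * record.fs))
        feat_rows.append(extract_event_features(clean.samples[lo:hi], record.fs).as_vector())
    feat_matrix = np.vstack(feat_rows)
    reduced = rf_pca_reduce(
        feat_matrix,
        encoded["Event"].to_numpy(),
        retain=config.features.retain_variance,
        seed=config.stage_seed("features"),
        feature_names=FEATURE_NAMES,
    )
    for j, name in enumerate(reduced.component_names):
        encoded[name] = reduced.components[:, j]
    log.info(
        "features: %d -> %d components (%.1f%% variance)",
        feat_matrix.shape[1],
        reduced.components.shape[1],
        100 * reduced.explained_variance_fraction,
    )

    # --- dataset + model ---------------------------------------------------
    feature_cols = ["Sleep Stage", "Position", "Location", "Duration[s]"] + reduced.component_names
    data = build_sequences(encoded, steps=config.dataset.steps, feature_columns=feature_cols)
    weights = class_weights(dataset=data)
    hp = HyperParams(
        n_recurrent_layers=config.train.n_recurrent_layers,
        units_per_layer=config.train.units_per_layer,
        dropout=config.train.dropout,
        dense_units=config.train.dense_units,
        batch_size=config.train.batch_size,
        learning_rate=config.train.learning_rate,
    )
    spec = build_model(hp, data.steps, data.inputs.shape[2], data.n_classes)
    model, history = train_model(
        spec, data, weights, epochs=config.train.epochs, seed=config.stage_seed("train")
    )
    (out / "history.json").write_text(json.dumps(history, indent=2))

    # --- evaluate ----------------------------------------------------------
    probs = model.predict_proba(data.inputs)
    valid = ~data.pad_mask
    y_true = data.targets[valid]
    y_probs = probs[valid]
    report = evaluate(
        y_true, y_probs, n_boot=config.evaluation.n_boot, seed=config.stage_seed("evaluate")
    )

    # --- interpret ---------------------------------------------------------
    n_bg = min(100, len(data.inputs))
    attr = attribute(model, data.inputs[:n_bg], data.inputs[:n_bg])
    per_step, per_feature, heatmap = aggregate_attributions(attr)

    # --- CAP rate ----------------------------------------------------------
    labels = list(table.frame["Sleep Stage"])
    rate, pathological = detect_mod.cap_rate(
        labels, pathology_threshold_pct=config.cap_rate.pathology_threshold_pct
    )

    result = {
        "explained_variance_pct": 100 * reduced.explained_variance_fraction,
        "n_components": reduced.components.shape[1],
        "n_detected_events": len(detected),
        "n_sequences": len(sequences),
        "sequence_stages": [s.mapped_stage for s in sequences],
        "accuracy": report.accuracy,
        "kappa": report.kappa,
        "reliability": report.reliability,
        "per_class_auc": None if report.auc is None else report.auc.tolist(),
        "cap_rate_pct": rate,
        "pathological": pathological,
        "attribution_per_step": per_step.tolist(),
        "attribution_per_feature": dict(zip(data.feature_names, per_feature.tolist())),
        "attribution_heatmap_shape": list(heatmap.shape),
    }
    (out / "report.json").write_text(json.dumps(result, indent=2, sort_keys=True))
    return result


def load_edf(path: str | Path, channel: str | None = None) -> EEGRecord:
    """Read one EEG channel from an EDF file (requires the optional mne extra)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("EDF input needs mne: pip install capscan[edf]") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="ERROR")
    name = channel or raw.ch_names[0]
    data = raw.get_data(picks=[name])[0] * 1e6  # volts -> microvolts
    return EEGRecord(samples=data, fs=float(raw.info["sfreq"]), channel=name)


__all__ = ["run_pipeline", "default_event_plan", "load_edf", "CleanEEG"]
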