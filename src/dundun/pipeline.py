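"""End-to-end stage drivers shared by the CLI and the analysis scripts.

Each stage reads/writes tidy CSV artifacts keyed by ``stimulus_id`` (and
``participant_id`` for behavioral tables).  Floats are written with 12
significant digits so a fixed seed reproduces artifacts byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as bhv
from . import features as feat
from . import glmm
from . import modulation as mod
from . import stats as st
from .audio_io import AudioRecording, compute_frame_features, load_audio, save_audio
from .segmentation import apply_manual_onsets, detect_onsets
from .synthetic import CorpusConfig, ListenerConfig, make_corpus, simulate_listeners

FLOAT_FORMAT = "%.12g"


def write_csv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def extract_stimulus_features(
    rec: AudioRecording,
    annotations: pd.DataFrame | None = None,
    compute_ams: bool = True,
):
    """Full acoustic battery for one recording.

    Returns ``(notes, summary)`` where ``notes`` is the per-note table and
    ``summary`` the per-stimulus feature row (including the modulation
    spectrum peak and pulse clarity).  If ``annotations`` contains rows for
    this stimulus they override the automatic onsets.
    """
    frames = compute_frame_features(rec)
    onsets = detect_onsets(frames)
    if annotations is not None and (
        annotations["stimulus_id"] == rec.stimulus_id
    ).any():
        onsets = apply_manual_onsets(onsets, annotations, duration_ms=rec.duration_ms)
    notes = feat.aggregate_notes(frames, onsets)
    ams = mod.amplitude_modulation_spectrum(rec) if compute_ams else None
    clarity = mod.pulse_clarity(rec, frames=frames)
    summary = feat.summarize_stimulus(
        notes,
        ams_peak_hz=ams.peak_hz if ams is not None else np.nan,
        pulse_clarity=clarity,
        intended_category=rec.intended_category,
    )
    return notes, summary, ams


def run_simulate(outdir, corpus_cfg=None, listener_cfg=None, write_wavs: bool = True):
    """Generate the synthetic corpus: audio, ground-truth onsets and notes.

    Listener responses are simulated later (``run_all``) from the *measured*
    stimulus features, so the response model sees the same inputs the
    perception GLMM will be fit on.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    corpus_cfg = corpus_cfg or CorpusConfig()
    recordings, onset_lists, notes = make_corpus(corpus_cfg)
    write_csv(notes, outdir / "ground_truth.csv")
    gt_onsets = pd.concat(
        [
            pd.DataFrame({"stimulus_id": ol.stimulus_id, "onset_ms": ol.onsets_ms})
            for ol in onset_lists
        ]
    )
    write_csv(gt_onsets, outdir / "ground_truth_onsets.csv")
    if write_wavs:
        wav_dir = outdir / "wav"
        wav_dir.mkdir(exist_ok=True)
        for rec in recordings:
            save_audio(wav_dir / f"{rec.stimulus_id}.wav", rec)
    (outdir / "config.json").write_text(
        json.dumps({"corpus": asdict(corpus_cfg)}, indent=2, default=list)
    )
    return recordings, onset_lists, notes


def run_features(
    recordings,
    outdir,
    annotations: pd.DataFrame | None = None,
    compute_ams: bool = True,
):
    """Acoustic battery over a corpus; writes notes.csv, stimuli.csv, ams.csv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    all_notes, summaries, ams_rows = [], [], []
    for rec in recordings:
        notes, summary, ams = extract_stimulus_features(rec, annotations, compute_ams)
        all_notes.append(notes)
        summaries.append(summary)
        if ams is not None:
            ams_rows.append(
                pd.DataFrame(
                    {
                        "stimulus_id": rec.stimulus_id,
                        "freq_hz": ams.freqs_hz,
                        "amplitude": ams.amplitude,
                    }
                )
            )
    notes = pd.concat(all_notes, ignore_index=True)
    stimuli = pd.DataFrame(summaries)
    write_csv(notes, outdir / "notes.csv")
    write_csv(stimuli, outdir / "stimuli.csv")
    if ams_rows:
        write_csv(pd.concat(ams_rows, ignore_index=True), outdir / "ams.csv")
    dens = group_densities(notes, stimuli)
    if not dens.empty:
        write_csv(dens, outdir / "densities.csv")
    return notes, stimuli


def group_densities(notes: pd.DataFrame, stimuli: pd.DataFrame, n_grid: int = 128) -> pd.DataFrame:
    """Per-group probability densities of the note-level measures.

    One row per (group, measure, grid point); groups are the intended
    categories of the stimuli.  Measures with too few or degenerate values
    in a group are skipped.
    """
    cat = stimuli.set_index("stimulus_id")["intended_category"]
    df = notes.assign(intended_category=notes["stimulus_id"].map(cat))
    ratios = {
        g: feat.interval_ratios(sub["ioi_ms"].to_numpy())
        for g, sub in df.groupby("intended_category")
    }
    rows = []
    measures = {
        "pitch": "pitch", "intensity": "intensity", "entropy": "entropy", "ioi_ms": "ioi_ms",
    }
    for group, sub in df.groupby("intended_category"):
        series = {name: sub[col].dropna().to_numpy() for name, col in measures.items()}
        series["interval_ratio"] = ratios.get(group, np.empty(0))
        for name, vals in series.items():
            vals = vals[np.isfinite(vals)]
            if vals.size < 5 or np.ptp(vals) == 0:
                continue
            grid = np.linspace(vals.min(), vals.max(), n_grid)
            dens = feat.probability_density(vals, grid)
            rows.append(pd.DataFrame({
                "intended_category": group, "measure": name, "grid": grid, "density": dens,
            }))
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["intended_category", "measure", "grid", "density"]
    )


def run_group_tests(stimuli: pd.DataFrame, outdir):
    outdir = Path(outdir)
    tests = st.group_feature_tests(stimuli)
    write_csv(tests, outdir / "group_tests.csv")
    return tests


def run_behavior(responses: pd.DataFrame, outdir):
    """Score listener responses; writes metrics.csv, confusion.csv, confidence.csv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    metrics = bhv.participant_metrics(responses)
    pooled = bhv.confusion(responses, by="pooled")
    summary = {
        "pooled_accuracy": bhv.accuracy(pooled),
        "pooled_mcc": bhv.mcc(pooled),
        "mean_participant_mcc": float(metrics["mcc"].mean()),
        **{k: getattr(pooled, k) for k in ("TP", "FP", "FN", "TN")},
        **bhv.group_mcc_test(responses),
    }
    write_csv(metrics, outdir / "metrics.csv")
    write_csv(
        pd.DataFrame([{k: getattr(pooled, k) for k in ("TP", "FP", "FN", "TN")}]),
        outdir / "confusion.csv",
    )
    write_csv(bhv.confidence_summary(responses), outdir / "confidence.csv")
    (outdir / "behavior_summary.json").write_text(json.dumps(summary, indent=2))
    return metrics, summary


def run_model(responses: pd.DataFrame, stimuli: pd.DataFrame, outdir):
    """VIF screen + perception GLMM; writes model_terms.csv, model_fit.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    candidates = [c for c in glmm.DEFAULT_ACOUSTIC if c in stimuli.columns]
    screen = st.vif_screen(stimuli[candidates])
    result = glmm.fit_perception_glmm(responses, stimuli, acoustic=screen["retained"])
    write_csv(result.terms, outdir / "model_terms.csv")
    fit = {
        "var_participant": result.var_participant,
        "var_stimulus": result.var_stimulus,
        "marginal_r2": result.marginal_r2,
        "conditional_r2": result.conditional_r2,
        "prediction_accuracy": result.prediction_accuracy,
        "prediction_mcc": result.prediction_mcc,
        "prediction_accuracy_marginal": result.prediction_accuracy_marginal,
        "prediction_mcc_marginal": result.prediction_mcc_marginal,
        "loglik": result.loglik,
        "n_obs": result.n_obs,
        "vif_removed": [[name, v] for name, v in screen["removed"]],
        "vif_retained": screen["retained"],
    }
    (outdir / "model_fit.json").write_text(json.dumps(fit, indent=2))
    return result, screen


def run_all(outdir, seed: int = 0, write_wavs: bool = False):
    """Fully synthetic end-to-end run: simulate -> features -> behavior -> model."""
    outdir = Path(outdir)
    corpus_cfg = CorpusConfig(seed=seed)
    recordings, onset_lists, gt_notes = run_simulate(
        outdir / "simulate", corpus_cfg, write_wavs=write_wavs
    )
    notes, stimuli = run_features(recordings, outdir / "features")
    run_group_tests(stimuli, outdir / "features")
    listener_cfg = ListenerConfig(seed=seed + 1)
    responses = simulate_listeners(listener_cfg, stimuli)
    write_csv(responses, outdir / "behavior" / "responses.csv")
    metrics, summary = run_behavior(responses, outdir / "behavior")
    result, screen = run_model(responses, stimuli, outdir / "model")
    return {
        "stimuli": stimuli,
        "responses": responses,
        "metrics": metrics,
        "behavior_summary": summary,
        "model": result,
        "vif_screen": screen,
    }
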