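"""Note-level and consecutive-note acoustic measures.

The battery follows a two-tier design: *note level* measures (pitch height,
intensity, Wiener-entropy timbre, inter-onset interval) and *consecutive
note* measures (absolute differences of the scaled tracks, and the
two-interval ratio i1/(i1+i2)).  Scaling to [0, 1] is done within recording
on the millisecond-wise tracks, between the 0.5th and 99.5th percentiles so
isolated outliers do not set the range.  Group-level summaries use unscaled
units for level measures (Hz, envelope amplitude, log flatness, ms) and the
scaled values for change measures.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .audio_io import FrameFeatures
from .segmentation import OnsetList

__all__ = [
    "scale_within_recording",
    "aggregate_notes",
    "consecutive_changes",
    "interval_ratio",
    "interval_ratios",
    "summarize_stimulus",
    "probability_density",
]

NOTE_COLUMNS = [
    "stimulus_id",
    "note_index",
    "onset_ms",
    "pitch",
    "intensity",
    "entropy",
    "ioi_ms",
    "scaled_pitch",
    "scaled_intensity",
    "scaled_entropy",
]


def scale_within_recording(values: np.ndarray) -> np.ndarray:
    """Scale to [0, 1] between the 0.5th and 99.5th percentiles, clipped.

    Degenerate input (both percentiles equal) maps to 0.5 everywhere.  NaNs
    pass through as NaN.
    """
    v = np.asarray(values, dtype=np.float64)
    finite = np.isfinite(v)
    if finite.sum() < 2:
        raise ValueError("need at least 2 finite values to scale")
    lo, hi = np.percentile(v[finite], [0.5, 99.5])
    if hi <= lo:
        out = np.full(v.shape, 0.5)
        out[~finite] = np.nan
        return out
    return np.clip((v - lo) / (hi - lo), 0.0, 1.0)


def aggregate_notes(frames: FrameFeatures, onsets: OnsetList) -> pd.DataFrame:
    """Aggregate frame tracks into one row per detected note.

    A note spans [onset, next onset); the last note runs to the end of the
    recording.  Intensity and entropy are note means; pitch is the median of
    voiced frames (robust to glide ends), NaN if no frame in the span is
    voiced.  Scaled variants aggregate the within-recording scaled tracks
    over the same spans.
    """
    if len(onsets) == 0:
        warnings.warn(f"no onsets for stimulus {onsets.stimulus_id!r}; empty note table")
        return pd.DataFrame(columns=NOTE_COLUMNS)
    t = np.asarray(frames.times_ms)
    end_ms = t[-1] + frames.step_ms
    bounds = np.concatenate([onsets.onsets_ms, [end_ms]])
    if bounds[0] < t[0] - frames.step_ms or onsets.onsets_ms[-1] > end_ms:
        raise ValueError("onsets fall outside the frame time base")

    scaled = {
        "pitch": scale_within_recording(frames.pitch_hz)
        if np.isfinite(frames.pitch_hz).sum() >= 2
        else np.full_like(np.asarray(frames.pitch_hz, dtype=float), np.nan),
        "intensity": scale_within_recording(frames.envelope),
        "entropy": scale_within_recording(frames.wiener_entropy),
    }

    rows = []
    for i in range(len(onsets)):
        sel = (t >= bounds[i]) & (t < bounds[i + 1])
        pitch_span = frames.pitch_hz[sel]
        env_span = frames.envelope[sel]
        voiced = np.isfinite(pitch_span)
        # pitch median over frames where this note dominates the envelope:
        # quiet tail frames are often contaminated by the previous or next
        # note's ringing and would drag the median off the true level
        if voiced.any() and env_span.size:
            dominant = voiced & (env_span >= 0.25 * np.quantile(env_span, 0.9))
            if dominant.any():
                voiced = dominant
        ioi = bounds[i + 1] - bounds[i] if i < len(onsets) - 1 else np.nan
        rows.append(
            {
                "stimulus_id": frames.stimulus_id,
                "note_index": i,
                "onset_ms": bounds[i],
                "pitch": np.median(pitch_span[voiced]) if voiced.any() else np.nan,
                "intensity": env_span.mean() if sel.any() else np.nan,
                "entropy": frames.wiener_entropy[sel].mean() if sel.any() else np.nan,
                "ioi_ms": ioi,
                "scaled_pitch": np.median(scaled["pitch"][sel][voiced])
                if voiced.any()
                else np.nan,
                "scaled_intensity": scaled["intensity"][sel].mean() if sel.any() else np.nan,
                "scaled_entropy": scaled["entropy"][sel].mean() if sel.any() else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=NOTE_COLUMNS)


def consecutive_changes(notes: pd.DataFrame) -> pd.DataFrame:
    """Absolute differences of scaled pitch/intensity/entropy between
    consecutive notes; n-1 rows for n notes."""
    if len(notes) < 2:
        warnings.warn("fewer than 2 notes; no consecutive changes")
        return pd.DataFrame(
            columns=["stimulus_id", "pair_index", "pitch_change", "intensity_change", "entropy_change"]
        )
    out = pd.DataFrame(
        {
            "stimulus_id": notes["stimulus_id"].iloc[:-1].to_numpy(),
            "pair_index": np.arange(len(notes) - 1),
            "pitch_change": np.abs(np.diff(notes["scaled_pitch"].to_numpy())),
            "intensity_change": np.abs(np.diff(notes["scaled_intensity"].to_numpy())),
            "entropy_change": np.abs(np.diff(notes["scaled_entropy"].to_numpy())),
        }
    )
    return out


def interval_ratio(i1: float, i2: float) -> float:
    """Two-interval ratio i1/(i1+i2); 0.5 means local isochrony."""
    if not (i1 > 0 and i2 > 0):
        raise ValueError("intervals must be positive")
    return i1 / (i1 + i2)


def interval_ratios(iois_ms: np.ndarray) -> np.ndarray:
    """Ratios for overlapping interval pairs (i1,i2), (i2,i3), ..."""
    iois = np.asarray(iois_ms, dtype=np.float64)
    iois = iois[np.isfinite(iois)]
    if iois.size < 2:
        return np.empty(0)
    if np.any(iois <= 0):
        raise ValueError("intervals must be positive")
    return iois[:-1] / (iois[:-1] + iois[1:])


def summarize_stimulus(
    notes: pd.DataFrame,
    ams_peak_hz: float = np.nan,
    pulse_clarity: float = np.nan,
    intended_category: str = "unknown",
) -> pd.Series:
    """Per-stimulus summary: level means on unscaled units, change means on
    scaled units, plus the modulation-spectrum peak and pulse clarity."""
    if notes.empty:
        raise ValueError("cannot summarize an empty note table")
    changes = consecutive_changes(notes) if len(notes) >= 2 else None
    ratios = interval_ratios(notes["ioi_ms"].to_numpy())
    return pd.Series(
        {
            "stimulus_id": notes["stimulus_id"].iloc[0],
            "intended_category": intended_category,
            "n_notes": len(notes),
            "mean_pitch": notes["pitch"].mean(),
            "mean_intensity": notes["intensity"].mean(),
            "mean_timbre": notes["entropy"].mean(),
            "mean_ioi_ms": notes["ioi_ms"].mean(),
            "mean_pitch_change": changes["pitch_change"].mean() if changes is not None else np.nan,
            "mean_intensity_change": changes["intensity_change"].mean() if changes is not None else np.nan,
            "mean_timbre_change": changes["entropy_change"].mean() if changes is not None else np.nan,
            "mean_interval_ratio": ratios.mean() if ratios.size else np.nan,
            "ams_peak_hz": ams_peak_hz,
            "pulse_clarity": pulse_clarity,
        }
    )


def probability_density(values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Gaussian-kernel density (Silverman bandwidth) evaluated on ``grid``."""
    v = np.asarray(values, dtype=np.float64)
    v = v[np.isfinite(v)]
    if v.size < 5:
        raise ValueError("need at least 5 values for a density estimate")
    if np.ptp(v) == 0:
        raise ValueError("degenerate sample (all values identical)")
    kde = gaussian_kde(v, bw_method="silverman")
    return kde(np.asarray(grid, dtype=np.float64))
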