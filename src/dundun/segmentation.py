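"""Note segmentation from the amplitude envelope.

Onsets are found where a lightly smoothed envelope (Hodrick-Prescott trend,
lambda = 50) rises above a strongly smoothed adaptive baseline (lambda = 1e7).
Both lambdas assume the envelope's 1 kHz sampling (1 ms step).  A manual
annotation sidecar can override the automatic onsets per stimulus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import solveh_banded

from .audio_io import FrameFeatures

__all__ = ["OnsetList", "HPDecomposition", "hp_filter", "detect_onsets", "apply_manual_onsets"]


@dataclass
class OnsetList:
    stimulus_id: str
    onsets_ms: np.ndarray
    source: str = "auto"  # auto | manual | mixed

    def __post_init__(self) -> None:
        self.onsets_ms = np.asarray(self.onsets_ms, dtype=np.float64)
        if self.onsets_ms.size and np.any(np.diff(self.onsets_ms) <= 0):
            raise ValueError("onsets must be strictly increasing")
        if np.any(self.onsets_ms < 0):
            raise ValueError("onsets must be non-negative")
        if self.source not in ("auto", "manual", "mixed"):
            raise ValueError(f"unknown onset source {self.source!r}")

    def __len__(self) -> int:
        return int(self.onsets_ms.size)


@dataclass
class HPDecomposition:
    """Hodrick-Prescott trend of a sequence; ``lam`` is the smoothing weight."""

    trend: np.ndarray
    lam: float


def hp_filter(signal: np.ndarray, lam: float) -> HPDecomposition:
    """Hodrick-Prescott trend filter.

    Solves ``(I + lam * D2' D2) tau = x`` where ``D2`` is the second-difference
    operator, i.e. the trend minimizing squared fit error plus ``lam`` times
    the squared curvature.  Solved as a symmetric pentadiagonal banded system.
    """
    x = np.asarray(signal, dtype=np.float64)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("signal must be 1-D with length >= 3")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    if not lam > 0:
        raise ValueError("lambda must be positive")
    n = x.size
    # D2'D2 bands: diag [1,5,6,...,6,5,1], 1st off-diag [-2,-4,...,-4,-2], 2nd off-diag 1
    d0 = np.full(n, 6.0)
    d0[[0, -1]] = 1.0
    d0[[1, -2]] = 5.0
    d1 = np.full(n - 1, -4.0)
    d1[[0, -1]] = -2.0
    d2 = np.ones(n - 2)
    ab = np.zeros((3, n))
    ab[0] = 1.0 + lam * d0
    ab[1, : n - 1] = lam * d1
    ab[2, : n - 2] = lam * d2
    trend = solveh_banded(ab, x, lower=True)
    return HPDecomposition(trend=trend, lam=float(lam))


def detect_onsets(
    frames: FrameFeatures,
    lambda_smooth: float = 50.0,
    lambda_trend: float = 1e7,
    min_gap_ms: float = 30.0,
    noise_floor_k: float = 0.65,
    max_rise_fraction: float = 0.04,
    baseline_fraction: float = 0.4,
) -> OnsetList:
    """Detect note onsets from the amplitude envelope.

    Candidate onsets are the rising segments (local minimum to the next
    local maximum) of ``d(t) = HP(env, lambda_smooth) - HP(env,
    lambda_trend)``; a rise is accepted when its magnitude exceeds

    * ``noise_floor_k`` times the MAD of ``d`` (noise floor),
    * ``max_rise_fraction`` of the largest rise in the recording (so noise
      wiggles in sparse recordings are rejected), and
    * ``baseline_fraction`` of the envelope level at the rise's start (so
      beating ripples between overlapping decaying notes, which are small
      rises riding on a high residual envelope, are rejected),

    and falls at least ``min_gap_ms`` after the previous accepted onset.
    The onset time is the point of steepest ascent within the rise.  All
    three thresholds are relative, so detection is invariant to global gain.
    """
    env = np.asarray(frames.envelope, dtype=np.float64)
    if env.size < 3 or not np.any(env > 0):
        return OnsetList(frames.stimulus_id, np.empty(0))
    d = hp_filter(env, lambda_smooth).trend - hp_filter(env, lambda_trend).trend
    mad = np.median(np.abs(d - np.median(d)))

    dd = np.diff(d)
    sign = np.sign(dd)
    turns = np.flatnonzero(np.diff(sign) != 0) + 1
    rises: list[tuple[int, int, float]] = []
    last_min = 0 if dd[0] > 0 else None
    for t in list(turns) + [d.size - 1]:
        s = sign[t] if t < sign.size else -1.0
        if s > 0 and last_min is None:
            last_min = t
        elif s <= 0 and last_min is not None:
            rises.append((last_min, t, d[t] - d[last_min]))
            last_min = None
    if not rises:
        return OnsetList(frames.stimulus_id, np.empty(0))

    mags = np.array([m for _, _, m in rises])
    floor = max(noise_floor_k * mad, max_rise_fraction * mags.max())
    if floor <= 0:
        floor = 1e-12 * max(env.max(), 1.0)

    onsets: list[float] = []
    for i, j, m in rises:
        if m < floor or m < baseline_fraction * env[i]:
            continue
        loc = i + int(np.argmax(np.diff(d[i : j + 1])))
        t = float(frames.times_ms[loc])
        if onsets and t - onsets[-1] < min_gap_ms:
            continue
        onsets.append(t)
    return OnsetList(frames.stimulus_id, np.asarray(onsets))


def apply_manual_onsets(
    auto: OnsetList,
    annotation: pd.DataFrame,
    duration_ms: float | None = None,
    merge: bool = False,
) -> OnsetList:
    """Replace (or merge with) automatic onsets using a manual annotation.

    ``annotation`` needs columns ``stimulus_id`` and ``onset_ms``; rows for
    other stimuli are ignored.  An annotation that matches the stimulus but
    contains no rows is rejected as ambiguous.
    """
    required = {"stimulus_id", "onset_ms"}
    if not required.issubset(annotation.columns):
        raise ValueError(f"annotation must have columns {sorted(required)}")
    rows = annotation[annotation["stimulus_id"] == auto.stimulus_id]
    if rows.empty:
        raise ValueError(f"annotation contains no onsets for stimulus {auto.stimulus_id!r}")
    times = np.asarray(rows["onset_ms"], dtype=np.float64)
    if np.any(np.diff(times) <= 0):
        raise ValueError("manual onsets must be strictly increasing")
    if duration_ms is not None and np.any((times < 0) | (times > duration_ms)):
        raise ValueError("manual onsets fall outside the recording duration")
    if merge:
        merged = np.unique(np.concatenate([auto.onsets_ms, times]))
        return OnsetList(auto.stimulus_id, merged, source="mixed")
    return OnsetList(auto.stimulus_id, times, source="manual")
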