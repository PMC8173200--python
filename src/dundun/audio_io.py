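"""Audio loading and millisecond-resolution descriptor tracks.

Every downstream stage (segmentation, note-level features, pulse clarity)
consumes the three frame tracks computed here: amplitude envelope, Wiener
entropy (log spectral flatness) and a fundamental-frequency track, all on a
shared 1 ms time base.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import resample_poly

__all__ = [
    "AudioRecording",
    "FrameFeatures",
    "load_audio",
    "compute_frame_features",
]

CATEGORIES = ("music", "speech", "unknown")


@dataclass
class AudioRecording:
    """Mono waveform with sampling rate and stimulus identity.

    Parameters
    ----------
    samples : ndarray
        Mono waveform, arbitrary amplitude units (float64).
    rate : float
        Sampling rate in Hz, > 0.
    stimulus_id : str
        Identifier used to key all downstream tables.
    intended_category : str
        ``"music"``, ``"speech"`` or ``"unknown"``.
    """

    samples: np.ndarray
    rate: float
    stimulus_id: str
    intended_category: str = "unknown"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim == 2:  # stereo -> mono by channel mean
            self.samples = self.samples.mean(axis=1)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D (or 2-D stereo) array")
        if not self.rate > 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        if self.intended_category not in CATEGORIES:
            raise ValueError(
                f"intended_category must be one of {CATEGORIES}, "
                f"got {self.intended_category!r}"
            )

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate

    @property
    def duration_ms(self) -> float:
        return 1000.0 * self.samples.size / self.rate


@dataclass
class FrameFeatures:
    """Frame-wise descriptor tracks on a shared 1 ms grid.

    ``envelope`` and ``wiener_entropy`` use a 10 ms analysis window;
    ``pitch_hz`` uses its own, longer window (a 10 ms window cannot resolve
    periods down to 40 Hz) but is sampled on the same grid.  ``pitch_hz`` is
    NaN where the frame is unvoiced or tracking confidence is too low.
    """

    times_ms: np.ndarray
    envelope: np.ndarray
    wiener_entropy: np.ndarray
    pitch_hz: np.ndarray
    stimulus_id: str = ""
    step_ms: float = 1.0

    def __post_init__(self) -> None:
        n = len(self.times_ms)
        if not (len(self.envelope) == len(self.wiener_entropy) == len(self.pitch_hz) == n):
            raise ValueError("all frame tracks must share one time base")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_ms": self.times_ms,
                "envelope": self.envelope,
                "wiener_entropy": self.wiener_entropy,
                "pitch_hz": self.pitch_hz,
            }
        )


def load_audio(path, stimulus_id: str | None = None, *, intended_category: str = "unknown",
               peak_normalize: bool = False) -> AudioRecording:
    """Read a PCM/float WAV file as a mono :class:`AudioRecording`.

    Stereo files are averaged to mono.  Integer PCM is rescaled to [-1, 1).
    ``peak_normalize=True`` rescales so the absolute peak is 1.0.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"audio file not found: {path}")
    try:
        rate, data = wavfile.read(str(path))
    except Exception as exc:  # noqa: BLE001 - re-raise with the path named
        raise ValueError(f"unreadable WAV file: {path} ({exc})") from exc
    if data.size == 0:
        raise ValueError(f"empty audio file: {path}")
    data = np.asarray(data)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / float(np.iinfo(data.dtype).max + 1)
    else:
        data = data.astype(np.float64)
    rec = AudioRecording(
        samples=data,
        rate=float(rate),
        stimulus_id=stimulus_id if stimulus_id is not None else path.stem,
        intended_category=intended_category,
    )
    if peak_normalize:
        peak = np.max(np.abs(rec.samples))
        if peak > 0:
            rec.samples = rec.samples / peak
    return rec


def save_audio(path, rec: AudioRecording) -> None:
    """Write a recording as 16-bit PCM WAV (clipped at full scale)."""
    x = np.clip(rec.samples, -1.0, 1.0)
    wavfile.write(str(path), int(round(rec.rate)), (x * 32767.0).astype(np.int16))


def _window_sums(x2: np.ndarray, starts: np.ndarray, win: int) -> np.ndarray:
    cs = np.concatenate(([0.0], np.cumsum(x2)))
    return cs[starts + win] - cs[starts]


def _frame_matrix(x: np.ndarray, starts: np.ndarray, win: int) -> np.ndarray:
    idx = starts[:, None] + np.arange(win)[None, :]
    return x[idx]


def _wiener_entropy_frames(frames: np.ndarray) -> np.ndarray:
    """Log spectral flatness (log geometric/arithmetic mean of power) per frame.

    Always <= 0 by the AM-GM inequality; ~0 for spectrally flat frames, strongly
    negative for tonal ones.  A raw periodogram of white noise is biased to about
    -0.58 rather than 0 (Euler-Mascheroni constant); we keep the raw estimate.
    """
    win = frames.shape[1]
    spec = np.fft.rfft(frames * np.hanning(win), axis=1)
    power = np.abs(spec[:, 1:]) ** 2  # drop DC
    # floor relative to the loudest frame so silence does not produce -inf/NaN
    floor = max(power.max(), np.finfo(float).tiny) * 1e-14
    power = np.maximum(power, floor)
    log_gm = np.mean(np.log(power), axis=1)
    log_am = np.log(np.mean(power, axis=1))
    return np.minimum(log_gm - log_am, 0.0)


def _pitch_track(
    x: np.ndarray,
    rate: float,
    centers_s: np.ndarray,
    fmin: float,
    fmax: float,
    window_s: float,
    voicing_threshold: float,
    silence_rms: float,
) -> np.ndarray:
    """Normalized-autocorrelation pitch per frame center; NaN where unvoiced.

    The signal is decimated to ~11 kHz first (ample for f0 <= 600 Hz) and the
    lag with the highest normalized autocorrelation in [1/fmax, 1/fmin] wins,
    refined by parabolic interpolation.
    """
    down = max(1, int(round(rate / 11025.0)))
    if down > 1:
        x = resample_poly(x, 1, down)
        rate = rate / down
    win = int(round(window_s * rate))
    lag_min = max(2, int(np.floor(rate / fmax)))
    lag_max = int(np.ceil(rate / fmin))
    if lag_max + 2 >= win:
        raise ValueError("pitch window too short for the requested minimum frequency")

    starts = np.clip((centers_s * rate).astype(np.int64) - win // 2, 0, max(0, x.size - win))
    keep = starts + win <= x.size
    pitch = np.full(centers_s.shape, np.nan)
    if not np.any(keep):
        return pitch
    frames = _frame_matrix(x, starts[keep], win)
    frames = frames - frames.mean(axis=1, keepdims=True)

    nfft = int(2 ** np.ceil(np.log2(win + lag_max + 1)))
    spec = np.fft.rfft(frames, n=nfft, axis=1)
    acf = np.fft.irfft(spec * np.conj(spec), n=nfft, axis=1)[:, : lag_max + 2]

    e = frames**2
    cs = np.concatenate([np.zeros((frames.shape[0], 1)), np.cumsum(e, axis=1)], axis=1)
    total = cs[:, -1]
    lags = np.arange(lag_max + 2)
    m0 = cs[:, win - lags]          # energy of x[0 : win-lag]
    m1 = total[:, None] - cs[:, lags]  # energy of x[lag : win]
    denom = np.sqrt(np.maximum(m0 * m1, np.finfo(float).tiny))
    r = acf / denom

    band = r[:, lag_min : lag_max + 1]
    # avoid octave-down errors: among local peaks scoring at least 0.68 of
    # the global maximum, take the shortest lag (the true period, not its
    # multiples).  The margin is safely above the relative ACF strength of
    # the strongest even partial (~0.15) yet tolerant of period peaks
    # weakened by overlapping note tails.
    rmax = band.max(axis=1, keepdims=True)
    interior = band[:, 1:-1]
    is_peak = (interior >= band[:, :-2]) & (interior >= band[:, 2:])
    candidate = np.zeros_like(band, dtype=bool)
    candidate[:, 1:-1] = is_peak & (interior >= 0.68 * rmax)
    has_peak = candidate.any(axis=1)
    first_peak = np.argmax(candidate, axis=1)  # first True = shortest lag
    best = np.where(has_peak, first_peak, np.argmax(band, axis=1)) + lag_min
    rows = np.arange(r.shape[0])
    rbest = r[rows, best]
    # parabolic refinement of the lag
    r_m1, r_p1 = r[rows, best - 1], r[rows, best + 1]
    denom_p = r_m1 - 2 * rbest + r_p1
    delta = np.divide(
        0.5 * (r_m1 - r_p1),
        denom_p,
        out=np.zeros_like(denom_p),
        where=np.abs(denom_p) > 1e-12,
    )
    delta = np.clip(delta, -0.5, 0.5)
    f0 = rate / (best + delta)

    frame_rms = np.sqrt(total / win)
    voiced = (rbest >= voicing_threshold) & (frame_rms > silence_rms)
    f0 = np.where(voiced, f0, np.nan)
    pitch[keep] = f0
    return pitch


def compute_frame_features(
    rec: AudioRecording,
    window_ms: float = 10.0,
    step_ms: float = 1.0,
    *,
    pitch_fmin: float = 40.0,
    pitch_fmax: float = 600.0,
    pitch_window_ms: float = 50.0,
    voicing_threshold: float = 0.3,
    envelope_kind: str = "rms",
) -> FrameFeatures:
    """Compute envelope, Wiener entropy and pitch on a 1 ms grid.

    Envelope is the windowed RMS of the waveform by default
    (``envelope_kind="hilbert"`` switches to the mean Hilbert magnitude per
    window).  Wiener entropy is the log ratio of geometric to arithmetic mean
    of the windowed power spectrum.  Pitch uses a normalized-autocorrelation
    tracker restricted to [``pitch_fmin``, ``pitch_fmax``] Hz.
    """
    if window_ms < step_ms:
        raise ValueError("window_ms must be >= step_ms")
    x, rate = rec.samples, rec.rate
    win = int(round(window_ms * rate / 1000.0))
    if win < 2 or x.size < win:
        raise ValueError(
            f"recording {rec.stimulus_id!r} is shorter than one analysis window"
        )
    # drift-free frame starts: nominal times k*step_ms, nearest-sample indexing
    step_samples = step_ms * rate / 1000.0
    n_frames = int((x.size - win) // step_samples) + 1
    starts = np.round(np.arange(n_frames) * step_samples).astype(np.int64)
    starts = starts[starts + win <= x.size]
    times_ms = np.arange(starts.size) * step_ms

    if envelope_kind == "rms":
        env = np.sqrt(_window_sums(x**2, starts, win) / win)
    elif envelope_kind == "hilbert":
        from scipy.signal import hilbert

        mag = np.abs(hilbert(x))
        env = _window_sums(mag, starts, win) / win
    else:
        raise ValueError(f"unknown envelope_kind {envelope_kind!r}")

    frames = _frame_matrix(x, starts, win)
    went = _wiener_entropy_frames(frames)

    silence_rms = 1e-5 * max(np.max(env), np.finfo(float).tiny)
    pitch = _pitch_track(
        x,
        rate,
        centers_s=(starts + win / 2) / rate,
        fmin=pitch_fmin,
        fmax=pitch_fmax,
        window_s=pitch_window_ms / 1000.0,
        voicing_threshold=voicing_threshold,
        silence_rms=silence_rms,
    )

    return FrameFeatures(
        times_ms=times_ms,
        envelope=env,
        wiener_entropy=went,
        pitch_hz=pitch,
        stimulus_id=rec.stimulus_id,
        step_ms=step_ms,
    )
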