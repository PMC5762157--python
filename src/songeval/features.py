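"""Sound-Analysis-Pro-style acoustic features.

Per-frame feature tracks (Wiener entropy, frequency/amplitude modulation,
fundamental frequency via cepstrum, pitch goodness, center frequency, power
measures) computed from a short-time power spectrogram, and the 101-entry
summary-statistic vector used to embed each syllable in feature space
(10 features x 10 statistics + duration).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

log = logging.getLogger(__name__)

#: Per-frame features, in canonical column order.
FEATURE_NAMES = [
    "wiener_entropy",
    "frequency_modulation",
    "amplitude_modulation",
    "fundamental_frequency",
    "pitch_goodness",
    "center_frequency",
    "total_power",
    "d_total_power",
    "max_fm_within_freq",
    "max_am_across_power",
]

#: Subset of feature tracks used for time-warped (DTW) syllable comparison.
DTW_FEATURES = [
    "wiener_entropy",
    "frequency_modulation",
    "amplitude_modulation",
    "fundamental_frequency",
    "pitch_goodness",
]

#: Summary statistics computed per feature, in canonical order.
STAT_NAMES = [
    "mean",
    "sd",
    "max",
    "min",
    "onset",
    "middle",
    "offset",
    "trend_r",
    "t_max",
    "t_min",
]

DEFAULT_WINDOW_S = 0.00927
DEFAULT_OVERLAP_S = 0.00791
ENTROPY_FLOOR = -15.0


@dataclass
class Spectrogram:
    """Short-time power spectrogram (magnitude squared)."""

    power: np.ndarray  # (n_freqs, n_frames), >= 0
    freqs: np.ndarray  # Hz
    frame_times: np.ndarray  # seconds, strictly increasing
    window_s: float
    step_s: float
    sample_rate: float


@dataclass
class FeatureTrack:
    """Per-frame acoustic feature tracks for one syllable.

    ``data`` holds one column per entry of :data:`FEATURE_NAMES`; all columns
    share ``frame_times`` (seconds, relative to the syllable's own clock).
    """

    data: pd.DataFrame
    frame_times: np.ndarray
    syllable_id: str = ""
    voiced: np.ndarray | None = None

    def __post_init__(self) -> None:
        missing = [c for c in FEATURE_NAMES if c not in self.data.columns]
        if missing:
            raise ValueError(f"feature track missing columns: {missing}")
        if len(self.data) != len(self.frame_times):
            raise ValueError("frame_times length does not match data")

    @property
    def n_frames(self) -> int:
        return len(self.data)

    @property
    def duration(self) -> float:
        if self.n_frames < 2:
            return 0.0
        return float(self.frame_times[-1] - self.frame_times[0])

    def dtw_array(self) -> np.ndarray:
        """(n_frames, 5) array of the DTW feature subset."""
        return self.data[DTW_FEATURES].to_numpy(dtype=float)


def compute_spectrogram(
    waveform: np.ndarray,
    sample_rate: float,
    window_s: float = DEFAULT_WINDOW_S,
    overlap_s: float = DEFAULT_OVERLAP_S,
) -> Spectrogram:
    """Power spectrogram with the 9.27 ms window / 7.91 ms overlap defaults.

    The frame step is ``window_s - overlap_s`` (1.36 ms at defaults).

    Raises
    ------
    ValueError
        If the waveform is shorter than one analysis window.
    """
    waveform = np.asarray(waveform, dtype=float)
    nperseg = int(round(window_s * sample_rate))
    noverlap = int(round(overlap_s * sample_rate))
    if nperseg <= 0 or noverlap >= nperseg:
        raise ValueError("window must be positive and longer than overlap")
    if waveform.size < nperseg:
        raise ValueError(
            f"waveform ({waveform.size} samples) shorter than one "
            f"{nperseg}-sample window"
        )
    freqs, times, sxx = signal.spectrogram(
        waveform,
        fs=sample_rate,
        window="hann",
        nperseg=nperseg,
        noverlap=noverlap,
        detrend=False,
        scaling="spectrum",
        mode="magnitude",
    )
    return Spectrogram(
        power=sxx**2,
        freqs=freqs,
        frame_times=times,
        window_s=nperseg / sample_rate,
        step_s=(nperseg - noverlap) / sample_rate,
        sample_rate=sample_rate,
    )


def _cepstral_pitch(
    power: np.ndarray,
    sample_rate: float,
    f_min: float,
    f_max: float,
    eps: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Fundamental frequency and pitch goodness per frame via the real cepstrum.

    The cepstrum is the inverse FFT of the log power spectrum; its peak in the
    lag band [fs/f_max, fs/f_min] gives the pitch period, and the peak height
    is the goodness (amount of periodic energy).
    """
    n_freq, n_frames = power.shape
    log_p = np.log(power + eps)
    n_fft = 2 * (n_freq - 1)
    cep = np.fft.irfft(log_p, n=n_fft, axis=0)
    lag_lo = max(2, int(np.ceil(sample_rate / f_max)))
    lag_hi = min(n_fft // 2, int(np.floor(sample_rate / f_min)))
    if lag_hi <= lag_lo:
        return np.full(n_frames, f_min), np.zeros(n_frames)
    band = cep[lag_lo:lag_hi]
    peak = np.argmax(band, axis=0)
    goodness = band[peak, np.arange(n_frames)]
    f0 = sample_rate / (peak + lag_lo)
    return f0, np.maximum(goodness, 0.0)


def compute_feature_tracks(
    spec: Spectrogram,
    pitch_band: tuple[float, float] = (300.0, 8000.0),
    entropy_floor: float = ENTROPY_FLOOR,
    goodness_voiced_threshold: float = 0.1,
    syllable_id: str = "",
) -> FeatureTrack:
    """Per-frame feature tracks from a power spectrogram.

    Wiener entropy is log(geometric mean / arithmetic mean) of each frame's
    power spectrum (0 for flat/noise-like spectra, strongly negative for
    tonal frames, floored at ``entropy_floor``).  AM/FM are built from
    centered finite differences of the (log-)power spectrogram; pitch and
    goodness come from the cepstrum peak within ``pitch_band``; center
    frequency is the power-weighted mean frequency.
    """
    p = np.asarray(spec.power, dtype=float)
    n_freq, n_frames = p.shape
    if n_frames == 0:
        raise ValueError("empty spectrogram")
    t = spec.frame_times
    eps = max(p.max(), 1e-300) * 1e-12

    total_power = p.sum(axis=0)
    silent = total_power <= 0

    # Wiener entropy: mean(log p) - log(mean p), exact 0 for a flat spectrum.
    ent = np.log(p + eps).mean(axis=0) - np.log(p.mean(axis=0) + eps)
    ent = np.clip(ent, entropy_floor, 0.0)
    ent[silent] = entropy_floor

    center = (spec.freqs[:, None] * p).sum(axis=0) / np.maximum(total_power, eps)

    log_tp = np.log(total_power + eps)
    if n_frames >= 2:
        am = np.gradient(log_tp, t)
        d_tp = np.gradient(total_power, t)
    else:
        am = np.zeros(n_frames)
        d_tp = np.zeros(n_frames)

    log_p = np.log(p + eps)
    if n_frames >= 2:
        dl_dt = np.gradient(log_p, t, axis=1)
    else:
        dl_dt = np.zeros_like(log_p)
    if n_freq >= 2:
        dl_df = np.gradient(log_p, spec.freqs, axis=0)
    else:
        dl_df = np.zeros_like(log_p)

    # FM: angle of the temporal versus spectral gradient energy of log power,
    # power-weighted per frame so near-silent bins do not dominate, and with
    # both gradients expressed per grid step (dimensionless axes).
    w = p / np.maximum(total_power, eps)
    df_step = spec.freqs[1] - spec.freqs[0] if n_freq >= 2 else 1.0
    rms_t = np.sqrt((w * (dl_dt * spec.step_s) ** 2).sum(axis=0))
    rms_f = np.sqrt((w * (dl_df * df_step) ** 2).sum(axis=0))
    fm = np.arctan2(rms_t, rms_f)

    max_fm = np.abs(dl_dt).max(axis=0)
    if n_frames >= 2:
        dp_dt = np.gradient(p, t, axis=1)
    else:
        dp_dt = np.zeros_like(p)
    max_am = np.abs(dp_dt).max(axis=0) / np.maximum(total_power, eps)

    f0, goodness = _cepstral_pitch(p, spec.sample_rate, *pitch_band, eps=eps)
    voiced = goodness >= goodness_voiced_threshold

    data = pd.DataFrame(
        {
            "wiener_entropy": ent,
            "frequency_modulation": fm,
            "amplitude_modulation": am,
            "fundamental_frequency": f0,
            "pitch_goodness": goodness,
            "center_frequency": center,
            "total_power": total_power,
            "d_total_power": d_tp,
            "max_fm_within_freq": max_fm,
            "max_am_across_power": max_am,
        }
    )
    if silent.any():
        log.debug("%d silent frame(s): entropy floored", int(silent.sum()))
    return FeatureTrack(
        data=data, frame_times=np.asarray(t, float), syllable_id=syllable_id,
        voiced=voiced,
    )


def _pct_window(n: int, lo: float, hi: float) -> slice:
    """Inclusive frame window for a percent range (minimum one frame)."""
    i0 = int(round(lo / 100.0 * (n - 1)))
    i1 = int(round(hi / 100.0 * (n - 1)))
    i1 = max(i1, i0)
    return slice(i0, i1 + 1)


def summarize_features(track: FeatureTrack, duration: float | None = None) -> pd.Series:
    """The 101-entry summary vector for one syllable.

    For each of the 10 per-frame features: mean, standard deviation, maximum,
    minimum, onset (mean over the 1-3% frame window), middle (49-51%), offset
    (97-100%), correlation coefficient of the linear time trend, time of
    maximum and time of minimum (seconds from the first frame); plus the
    syllable duration as the final entry.  Single-frame tracks get sd and
    trend 0 (flagged via a debug log).
    """
    n = track.n_frames
    if n == 0:
        raise ValueError("empty feature track")
    if duration is None:
        duration = track.duration
    t_rel = track.frame_times - track.frame_times[0]
    out: dict[str, float] = {}
    for name in FEATURE_NAMES:
        x = track.data[name].to_numpy(dtype=float)
        out[f"{name}_mean"] = float(np.mean(x))
        out[f"{name}_sd"] = float(np.std(x, ddof=1)) if n > 1 else 0.0
        out[f"{name}_max"] = float(np.max(x))
        out[f"{name}_min"] = float(np.min(x))
        out[f"{name}_onset"] = float(np.mean(x[_pct_window(n, 1, 3)]))
        out[f"{name}_middle"] = float(np.mean(x[_pct_window(n, 49, 51)]))
        out[f"{name}_offset"] = float(np.mean(x[_pct_window(n, 97, 100)]))
        if n > 1 and np.std(x) > 0 and np.std(t_rel) > 0:
            out[f"{name}_trend_r"] = float(np.corrcoef(t_rel, x)[0, 1])
        else:
            out[f"{name}_trend_r"] = 0.0
        out[f"{name}_t_max"] = float(t_rel[int(np.argmax(x))])
        out[f"{name}_t_min"] = float(t_rel[int(np.argmin(x))])
    out["duration"] = float(duration)
    vec = pd.Series(out, name=track.syllable_id or None)
    assert len(vec) == 101
    return vec


def summary_table(tracks: list[FeatureTrack]) -> pd.DataFrame:
    """Stack summary vectors for many syllables (rows indexed by syllable id)."""
    rows = [summarize_features(tr) for tr in tracks]
    df = pd.DataFrame(rows)
    df.index = [tr.syllable_id for tr in tracks]
    return df
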