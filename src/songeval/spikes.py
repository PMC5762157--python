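"""Single-neuron spike-train statistics for singing sessions.

Segments continuous singing into episodes (300 ms gap rule), finds silent
baseline periods (>= 2 s, with a 2 s guard from any vocal or noise
annotation), and computes the per-neuron statistics: standardized response
strength (a paired-t-like statistic on singing vs local-baseline rates),
responsiveness tests, burst fraction, per-syllable firing rates with the
50 ms premotor window, baseline correction, linear spike-time warping,
sparseness (activity fraction), and firing-rate CV.

All intervals are half-open ``[onset, offset)``: closed on the left, open on
the right, so adjacent windows never double-count a spike.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

GAP_THRESHOLD_S = 0.3
BASELINE_MIN_LEN_S = 2.0
BASELINE_GUARD_S = 2.0
PRE_WINDOW_S = 0.05
BURST_ISI_S = 0.010
MIN_RENDITIONS = 40


@dataclass
class Episode:
    """A period of continuous singing (internal gaps < 300 ms)."""

    onset: float
    offset: float
    syllable_ids: list[str] = field(default_factory=list)

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class BaselinePeriod:
    """A silent interval >= 2 s, >= 2 s away from any annotated activity."""

    onset: float
    offset: float

    @property
    def duration(self) -> float:
        return self.offset - self.onset


def segment_episodes(
    segments: pd.DataFrame, gap_threshold: float = GAP_THRESHOLD_S
) -> list[Episode]:
    """Group time-ordered syllables into singing episodes.

    A new episode starts whenever the silent gap before a syllable is at
    least ``gap_threshold`` (a gap of exactly 300 ms splits).

    Raises
    ------
    ValueError
        If segments overlap or are not time-ordered.
    """
    seg = segments.sort_values("onset_s").reset_index(drop=True)
    on = seg["onset_s"].to_numpy(float)
    off = seg["offset_s"].to_numpy(float)
    if np.any(off <= on):
        raise ValueError("segment offsets must exceed onsets")
    if np.any(on[1:] < off[:-1]):
        raise ValueError("overlapping segments")
    episodes: list[Episode] = []
    start = 0
    for i in range(1, len(seg) + 1):
        if i == len(seg) or on[i] - off[i - 1] >= gap_threshold:
            episodes.append(
                Episode(
                    onset=float(on[start]),
                    offset=float(off[i - 1]),
                    syllable_ids=list(seg["syllable_id"].iloc[start:i]),
                )
            )
            start = i
    return episodes


def find_baselines(
    annotations: pd.DataFrame,
    record_span: tuple[float, float],
    min_len: float = BASELINE_MIN_LEN_S,
    guard: float = BASELINE_GUARD_S,
) -> list[BaselinePeriod]:
    """Silent baseline periods within a recording.

    ``annotations`` lists intervals of singing, calls and movement/cage
    noise (columns onset_s, offset_s).  Each maximal silent interval is
    trimmed by ``guard`` on both sides and kept if at least ``min_len``
    remains.
    """
    t0, t1 = record_span
    if len(annotations) == 0:
        lo, hi = t0 + guard, t1 - guard
        return [BaselinePeriod(lo, hi)] if hi - lo >= min_len else []
    ann = annotations.sort_values("onset_s")
    merged: list[list[float]] = []
    for _, row in ann.iterrows():
        a, b = float(row["onset_s"]), float(row["offset_s"])
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    gaps = []
    prev = t0
    for a, b in merged:
        gaps.append((prev, a))
        prev = max(prev, b)
    gaps.append((prev, t1))
    out = []
    for a, b in gaps:
        lo, hi = a + guard, b - guard
        if hi - lo >= min_len:
            out.append(BaselinePeriod(lo, hi))
    return out


def rate_in(spikes: np.ndarray, onset: float, offset: float) -> float:
    """Firing rate (spikes/s) in the half-open window [onset, offset)."""
    if offset <= onset:
        raise ValueError("empty window")
    n = np.searchsorted(spikes, offset, side="left") - np.searchsorted(
        spikes, onset, side="left"
    )
    return float(n) / (offset - onset)


def pair_local_baselines(
    episodes: list[Episode], baselines: list[BaselinePeriod]
) -> list[tuple[Episode, list[BaselinePeriod]]]:
    """Pair each singing episode with the two nearest-in-time baselines.

    The local baseline rate for an episode is the average over these two
    periods (one if only one exists); episodes with no available baseline
    are dropped with a log message.
    """
    if not baselines:
        return []
    b_mid = np.array([(b.onset + b.offset) / 2 for b in baselines])
    out = []
    for ep in episodes:
        mid = (ep.onset + ep.offset) / 2
        order = np.argsort(np.abs(b_mid - mid), kind="stable")[:2]
        out.append((ep, [baselines[i] for i in order]))
    return out


def episode_baseline_rates(
    spikes: np.ndarray,
    episodes: list[Episode],
    baselines: list[BaselinePeriod],
) -> tuple[np.ndarray, np.ndarray]:
    """Paired (singing, local-baseline) rates per episode."""
    pairs = pair_local_baselines(episodes, baselines)
    s, b = [], []
    for ep, locs in pairs:
        s.append(rate_in(spikes, ep.onset, ep.offset))
        b.append(np.mean([rate_in(spikes, x.onset, x.offset) for x in locs]))
    return np.asarray(s), np.asarray(b)


def response_strength(s_rates: np.ndarray, b_rates: np.ndarray) -> float:
    """Standardized response strength: paired, SE-normalized rate change.

    ``RS = (mean S - mean B) / sqrt((Var S + Var B - 2 Cov(S, B)) / n)``,
    which equals the paired t statistic on the per-episode differences
    (since ``Var(S - B) = Var S + Var B - 2 Cov``).  Positive = excited
    during singing, negative = suppressed.  Returns NaN (logged) when the
    paired variance is zero.
    """
    s = np.asarray(s_rates, float)
    b = np.asarray(b_rates, float)
    if s.shape != b.shape or s.size < 2:
        raise ValueError("need >= 2 paired singing/baseline rates")
    n = s.size
    var_d = np.var(s, ddof=1) + np.var(b, ddof=1) - 2 * np.cov(s, b, ddof=1)[0, 1]
    if var_d <= 0:
        if np.allclose(s, b):
            return 0.0 if np.mean(s) == np.mean(b) else np.nan
        log.warning("zero paired variance; response strength undefined")
        return np.nan
    return float((np.mean(s) - np.mean(b)) / np.sqrt(var_d / n))


def responsiveness_test(
    singing_rates: np.ndarray,
    baseline_rates: np.ndarray,
    alpha: float = 0.05,
) -> tuple[float, float, str]:
    """Two-sample test of singing vs baseline firing rate.

    An independent t-test is used (singing episodes and baseline periods
    differ in number); a neuron is ``excited`` or ``suppressed`` by the sign
    of the difference when p < alpha, else ``ns``.  Degenerate (zero
    variance in both groups) falls back to Mann-Whitney, logged.
    """
    s = np.asarray(singing_rates, float)
    b = np.asarray(baseline_rates, float)
    if s.size < 2 or b.size < 2:
        raise ValueError("need >= 2 values per group")
    if np.var(s) == 0 and np.var(b) == 0:
        if np.mean(s) == np.mean(b):
            return 0.0, 1.0, "ns"
        log.info("degenerate variances; using Mann-Whitney fallback")
        stat, p = stats.mannwhitneyu(s, b, alternative="two-sided")
    else:
        stat, p = stats.ttest_ind(s, b)
    flag = "ns"
    if p < alpha:
        flag = "excited" if np.mean(s) > np.mean(b) else "suppressed"
    return float(stat), float(p), flag


def burst_fraction(
    spikes: np.ndarray,
    intervals: list[tuple[float, float]],
    isi_threshold: float = BURST_ISI_S,
) -> float:
    """Fraction of interspike intervals shorter than 10 ms within intervals.

    ISIs are computed only between consecutive spikes falling inside the
    same interval (the denominator is the number of such ISIs).  Returns NaN
    (logged) when fewer than two spikes fall inside the intervals.
    """
    spikes = np.asarray(spikes, float)
    isis = []
    for a, b in intervals:
        sub = spikes[(spikes >= a) & (spikes < b)]
        if sub.size >= 2:
            isis.append(np.diff(sub))
    if not isis:
        log.warning("fewer than 2 spikes in intervals; burst fraction undefined")
        return np.nan
    isis = np.concatenate(isis)
    return float(np.mean(isis < isi_threshold))


def syllable_rate(
    spikes: np.ndarray,
    onset: float,
    offset: float,
    pre_window: float = PRE_WINDOW_S,
) -> float:
    """Firing rate over a syllable plus the 50 ms premotor window.

    Counts spikes in ``[onset - pre_window, offset)`` and divides by the
    window duration; the premotor window captures pre-syllable activity
    (the ~60 ms typical inter-syllable gap keeps windows from reaching the
    previous syllable).
    """
    return rate_in(spikes, onset - pre_window, offset)


def baseline_corrected_rate(rate: float, local_baseline_rate: float) -> float:
    """Syllable firing rate minus the local silent-baseline rate."""
    return rate - local_baseline_rate


def rendition_rate_table(
    spikes: np.ndarray,
    segments: pd.DataFrame,
    episodes: list[Episode],
    baselines: list[BaselinePeriod],
    pre_window: float = PRE_WINDOW_S,
) -> pd.DataFrame:
    """Per-rendition rates and baseline-corrected rates.

    Each syllable inherits the local-baseline rate of its enclosing episode
    (average of the two nearest baseline periods); renditions in episodes
    with no baseline are excluded with a log message.
    """
    pairs = pair_local_baselines(episodes, baselines)
    local = {}
    for ep, locs in pairs:
        b = np.mean([rate_in(spikes, x.onset, x.offset) for x in locs])
        for sid in ep.syllable_ids:
            local[sid] = b
    rows = []
    dropped = 0
    for _, row in segments.iterrows():
        sid = row["syllable_id"]
        if sid not in local:
            dropped += 1
            continue
        r = syllable_rate(spikes, row["onset_s"], row["offset_s"], pre_window)
        rows.append(
            {
                "syllable_id": sid,
                "rate": r,
                "baseline_rate": local[sid],
                "baseline_corrected_rate": baseline_corrected_rate(r, local[sid]),
            }
        )
    if dropped:
        log.info("%d rendition(s) without local baseline excluded", dropped)
    return pd.DataFrame(rows)


def linear_time_warp(
    spike_times: np.ndarray,
    onset: float,
    duration: float,
    reference_duration: float,
) -> np.ndarray:
    """Linearly stretch spike times to a type's reference duration.

    Syllables are aligned at onsets: ``t' = onset + (t - onset) * ref/dur``.
    Order is preserved (positive scale factor).
    """
    if reference_duration <= 0 or duration <= 0:
        raise ValueError("durations must be positive")
    t = np.asarray(spike_times, float)
    return onset + (t - onset) * (reference_duration / duration)


def activity_fraction(rates: np.ndarray) -> float:
    """Sparseness of firing across syllable types.

    ``AF = [1 - (sum r_i / n)^2 / (sum r_i^2 / n)] / (1 - 1/n)``: 0 for
    uniform rates (no selectivity), 1 when only one type drives firing.
    Undefined (NaN, logged) for all-zero rates.
    """
    r = np.asarray(rates, float)
    if r.size < 2:
        raise ValueError("need rates for >= 2 syllable types")
    if np.any(r < 0):
        raise ValueError("rates must be nonnegative")
    if np.all(r == 0) or np.mean(r**2) == 0:  # incl. underflow of tiny rates
        log.warning("all-zero rates; activity fraction undefined")
        return np.nan
    n = r.size
    af = (1.0 - (r.mean() ** 2) / np.mean(r**2)) / (1.0 - 1.0 / n)
    return float(af)


def cv_firing(rates: np.ndarray, ddof: int = 1) -> float:
    """Coefficient of variation (sd/mean) of syllable-based firing rates.

    Uses the sample standard deviation (``ddof=1``) by default.  A zero
    mean leaves the CV undefined; the neuron is excluded from CV analyses
    (NaN returned, logged).
    """
    r = np.asarray(rates, float)
    m = r.mean()
    if m == 0:
        log.info("zero mean rate; CV undefined, neuron excluded")
        return np.nan
    return float(np.std(r, ddof=ddof) / m)
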