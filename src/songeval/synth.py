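"""Synthetic tutor repertoires, juvenile singing sessions, and spike trains.

The generator plays the role of the recorded birds: a repertoire of K tutor
syllable templates, juvenile renditions produced as parametrically distorted
copies of those templates (the distortion magnitude ``delta`` is the
ground-truth dissimilarity to tutor), bout structure with inter-syllable
gaps, a subsong-to-plastic-song duration axis (exponential vs peaked
mixture), and inhomogeneous-Poisson spike trains whose within-syllable rate
is coupled to ground-truth tutor similarity through a signed coefficient
``beta``.

Two fidelity tiers are provided: a fast path that emits
:class:`~songeval.features.FeatureTrack` objects directly (the feature values
are exactly controllable), and a slow path that synthesizes PCM waveforms
(harmonic stack plus noise) so the acoustic feature extractor is exercised
end to end.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .features import FEATURE_NAMES, FeatureTrack

log = logging.getLogger(__name__)

DEFAULT_SAMPLE_RATE = 44100
DEFAULT_FRAME_STEP_S = 0.00136  # matches the feature extractor's frame step
BURST_DOUBLET_ISI_S = 0.004

DEFAULT_FEATURE_RANGES = {
    "f0_base": (500.0, 2400.0),  # Hz
    "f0_sweep_oct": (-0.6, 0.6),  # octaves over the syllable
    "duration": (0.06, 0.25),  # seconds
    "noise_fraction": (0.05, 0.55),
    "n_harmonics": (2, 6),
}

#: Minimum pairwise separation of templates in normalized parameter space.
SEPARATION_FLOOR = 0.45


@dataclass
class TutorTemplate:
    """One tutor syllable, described parametrically and as per-frame tracks."""

    type_id: str
    f0_track: np.ndarray  # Hz per frame
    harmonic_weights: np.ndarray
    amplitude_envelope: np.ndarray  # unitless per frame, peak 1
    noise_fraction: float
    duration: float  # seconds

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not (0.0 <= self.noise_fraction <= 1.0):
            raise ValueError("noise_fraction must lie in [0, 1]")
        if not np.all(np.isfinite(self.f0_track)) or np.any(self.f0_track <= 0):
            raise ValueError("f0_track must be finite and positive")


@dataclass
class DistortionSpec:
    """Distortion applied to a template; ``delta`` is the ground truth.

    ``delta = 0`` reproduces the template's own realization bit-exactly for a
    given seed.  ``components`` scales the individual distortion channels
    (per-feature jitter, time-warp factor range, additive spectral noise).
    """

    delta: float
    seed: int
    components: dict = field(
        default_factory=lambda: {
            "f0_jitter": 0.25,  # log-Hz scale of smooth pitch jitter at delta=1
            "time_warp": 0.35,  # log duration half-range at delta=1
            "noise_shift": 0.35,  # shift of noise_fraction at delta=1
            "envelope_jitter": 0.4,
            "spectral_noise": 0.25,  # additive noise amplitude at delta=1
        }
    )

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError("delta must be >= 0")


@dataclass
class NeuronProfile:
    """Forward model of one unit's firing during a session."""

    baseline_rate: float  # spikes/s during silence
    singing_gain: float = 1.0  # multiplicative; < 1 = singing-suppressed
    beta: float = 0.0  # signed coupling of log-rate to tutor similarity
    premotor_ramp: dict | None = None  # {"amplitude": sp/s, "lead_ms": float}
    burst_prob: float = 0.0
    rate_noise_sd: float = 0.0  # rendition-level lognormal sd at delta=0
    variability_coupling: float = 0.0  # extra lognormal sd per unit delta
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be >= 0")
        if self.premotor_ramp is not None:
            if self.premotor_ramp.get("lead_ms", 0.0) > 200.0:
                raise ValueError("ramp lead must be <= 200 ms")
        if not (0.0 <= self.burst_prob <= 1.0):
            raise ValueError("burst_prob must lie in [0, 1]")


@dataclass
class Session:
    """A simulated 'recording session': segments plus rendition realizations."""

    segments: pd.DataFrame  # syllable_id, onset_s, offset_s, true_type, true_delta
    renditions: list  # FeatureTrack (fast path) or (waveform, rate) (slow path)
    stage: float
    mode: str
    total_duration: float

    @property
    def delta_table(self) -> pd.DataFrame:
        return self.segments[["syllable_id", "true_delta"]]


def _template_params(template: TutorTemplate) -> np.ndarray:
    """Normalized parameter vector used for separation checks."""
    lo_f, hi_f = DEFAULT_FEATURE_RANGES["f0_base"]
    lo_d, hi_d = DEFAULT_FEATURE_RANGES["duration"]
    f0 = float(template.f0_track[0])
    sweep = float(np.log2(template.f0_track[-1] / template.f0_track[0]))
    return np.array(
        [
            (np.log(f0) - np.log(lo_f)) / (np.log(hi_f) - np.log(lo_f)),
            (sweep - DEFAULT_FEATURE_RANGES["f0_sweep_oct"][0])
            / (DEFAULT_FEATURE_RANGES["f0_sweep_oct"][1] - DEFAULT_FEATURE_RANGES["f0_sweep_oct"][0]),
            (template.duration - lo_d) / (hi_d - lo_d),
            (template.noise_fraction - DEFAULT_FEATURE_RANGES["noise_fraction"][0])
            / (DEFAULT_FEATURE_RANGES["noise_fraction"][1] - DEFAULT_FEATURE_RANGES["noise_fraction"][0]),
        ]
    )


def _draw_template(rng: np.random.Generator, ranges: dict, type_id: str,
                   frame_step: float) -> TutorTemplate:
    f0_base = np.exp(rng.uniform(*np.log(ranges["f0_base"])))
    sweep = rng.uniform(*ranges["f0_sweep_oct"])
    duration = rng.uniform(*ranges["duration"])
    noise_fraction = rng.uniform(*ranges["noise_fraction"])
    n_harm = rng.integers(ranges["n_harmonics"][0], ranges["n_harmonics"][1] + 1)
    weights = 1.0 / np.arange(1, n_harm + 1) ** rng.uniform(0.5, 1.5)
    weights /= weights.sum()
    n_frames = max(int(round(duration / frame_step)), 4)
    phase = np.linspace(0.0, 1.0, n_frames)
    f0_track = f0_base * 2.0 ** (sweep * phase)
    envelope = np.sin(np.pi * np.clip(phase, 0.02, 0.98)) ** 0.7
    return TutorTemplate(
        type_id=type_id,
        f0_track=f0_track,
        harmonic_weights=weights,
        amplitude_envelope=envelope,
        noise_fraction=float(noise_fraction),
        duration=float(duration),
    )


def make_tutor_repertoire(
    k: int,
    feature_ranges: dict | None = None,
    seed: int = 0,
    separation_floor: float = SEPARATION_FLOOR,
    max_tries: int = 5000,
    frame_step: float = DEFAULT_FRAME_STEP_S,
) -> list[TutorTemplate]:
    """Draw ``k`` tutor templates with a guaranteed parameter-space margin.

    Templates are rejection-sampled until every pair is at least
    ``separation_floor`` apart in normalized (log-f0, sweep, duration,
    noisiness) space, which guarantees that downstream dissimilarity between
    types exceeds the within-type scatter produced by moderate distortion.

    Raises
    ------
    ValueError
        If ``k < 1``.
    RuntimeError
        If the requested separation is infeasible at this ``k``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ranges = dict(DEFAULT_FEATURE_RANGES)
    if feature_ranges:
        ranges.update(feature_ranges)
    rng = np.random.default_rng(seed)
    templates: list[TutorTemplate] = []
    params: list[np.ndarray] = []
    tries = 0
    while len(templates) < k:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {k} templates with separation "
                f">= {separation_floor} after {max_tries} draws"
            )
        tries += 1
        cand = _draw_template(rng, ranges, f"tutor_{len(templates)}", frame_step)
        v = _template_params(cand)
        if all(np.linalg.norm(v - u) >= separation_floor for u in params):
            templates.append(cand)
            params.append(v)
    return templates


def _smooth_noise(rng: np.random.Generator, n: int, n_knots: int = 6) -> np.ndarray:
    """Smooth unit-scale noise track (cubic-ish via linear knot interpolation)."""
    knots = rng.standard_normal(max(n_knots, 2))
    x = np.linspace(0.0, 1.0, knots.size)
    return np.interp(np.linspace(0.0, 1.0, n), x, knots)


def _distorted_params(
    template: TutorTemplate,
    spec: DistortionSpec,
    rng: np.random.Generator,
    duration_override: float | None,
):
    """Apply the distortion channels; all perturbations scale with delta."""
    c = spec.components
    d = spec.delta
    n = template.f0_track.size
    f0 = template.f0_track * np.exp(d * c["f0_jitter"] * _smooth_noise(rng, n))
    warp = float(np.exp(d * c["time_warp"] * rng.uniform(-1.0, 1.0)))
    duration = template.duration * warp
    if duration_override is not None:
        duration = duration_override
    env = template.amplitude_envelope * np.exp(
        d * c["envelope_jitter"] * _smooth_noise(rng, n)
    )
    env = env / max(env.max(), 1e-12)
    nf = float(np.clip(
        template.noise_fraction + d * c["noise_shift"] * rng.uniform(-0.5, 1.0),
        0.0, 0.95,
    ))
    return f0, env, nf, duration


def _feature_track_from_params(
    f0: np.ndarray,
    env: np.ndarray,
    noise_fraction: float,
    duration: float,
    weights: np.ndarray,
    syllable_id: str,
    frame_step: float,
) -> FeatureTrack:
    """Analytic per-frame features of a parametric syllable (fast path)."""
    n_frames = max(int(round(duration / frame_step)), 4)
    phase = np.linspace(0.0, 1.0, n_frames)
    src = np.linspace(0.0, 1.0, f0.size)
    f0_t = np.interp(phase, src, f0)
    env_t = np.interp(phase, src, env)
    t = phase * duration
    dt = max(duration / (n_frames - 1), 1e-9)

    entropy = np.clip(-9.0 * (1.0 - noise_fraction) * env_t, -15.0, 0.0)
    fm = np.abs(np.gradient(np.log(f0_t), dt)) / 50.0
    total_power = env_t**2 + 1e-6
    am = np.gradient(np.log(total_power), dt) / 50.0
    d_tp = np.gradient(total_power, dt)
    goodness = 10.0 * (1.0 - noise_fraction) * env_t
    centroid_factor = float(np.sum(weights * np.arange(1, weights.size + 1)))
    center = f0_t * (centroid_factor * (1 - noise_fraction) + 4.0 * noise_fraction)
    data = pd.DataFrame(
        {
            "wiener_entropy": entropy,
            "frequency_modulation": fm,
            "amplitude_modulation": am,
            "fundamental_frequency": f0_t,
            "pitch_goodness": goodness,
            "center_frequency": center,
            "total_power": total_power,
            "d_total_power": d_tp,
            "max_fm_within_freq": np.abs(fm) * 2.0,
            "max_am_across_power": np.abs(am) * 2.0,
        }
    )[FEATURE_NAMES]
    return FeatureTrack(data=data, frame_times=t, syllable_id=syllable_id)


def _waveform_from_params(
    f0: np.ndarray,
    env: np.ndarray,
    noise_fraction: float,
    duration: float,
    weights: np.ndarray,
    rng: np.random.Generator,
    sample_rate: float,
    extra_noise: float,
) -> np.ndarray:
    """Harmonic-stack-plus-noise synthesis (slow path)."""
    n = max(int(round(duration * sample_rate)), 32)
    phase01 = np.linspace(0.0, 1.0, n)
    src = np.linspace(0.0, 1.0, f0.size)
    f0_s = np.interp(phase01, src, f0)
    env_s = np.interp(phase01, src, env)
    inst_phase = 2.0 * np.pi * np.cumsum(f0_s) / sample_rate
    harm = np.zeros(n)
    for h, w in enumerate(weights, start=1):
        if h * f0_s.max() < sample_rate / 2:
            harm += w * np.sin(h * inst_phase)
    noise = rng.standard_normal(n)
    x = env_s * ((1.0 - noise_fraction) * harm + noise_fraction * noise)
    if extra_noise > 0:
        x = x + extra_noise * rng.standard_normal(n)
    peak = np.max(np.abs(x))
    if peak > 0:
        x = 0.9 * x / peak
    return x


def render_rendition(
    template: TutorTemplate,
    spec: DistortionSpec,
    mode: str = "features",
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    frame_step: float = DEFAULT_FRAME_STEP_S,
    syllable_id: str = "",
    duration_override: float | None = None,
):
    """Render one juvenile rendition of a tutor template.

    Returns ``(realization, ground_truth_delta)`` where the realization is a
    :class:`FeatureTrack` (``mode="features"``) or ``(waveform, sample_rate)``
    (``mode="waveform"``).  Determinism: identical ``spec`` (delta, seed,
    components) gives an identical realization; ``delta=0`` returns the
    template's own realization for that seed.
    """
    rng = np.random.default_rng(spec.seed)
    f0, env, nf, duration = _distorted_params(template, spec, rng, duration_override)
    if mode == "features":
        out = _feature_track_from_params(
            f0, env, nf, duration, template.harmonic_weights, syllable_id, frame_step
        )
        return out, spec.delta
    if mode == "waveform":
        wav = _waveform_from_params(
            f0, env, nf, duration, template.harmonic_weights, rng,
            sample_rate, extra_noise=spec.delta * spec.components["spectral_noise"],
        )
        return (wav, sample_rate), spec.delta
    raise ValueError(f"unknown mode {mode!r}")


def render_tutor_set(
    repertoire: list[TutorTemplate],
    mode: str = "features",
    seed: int = 0,
    **kw,
):
    """Undistorted realizations of all tutor templates (delta = 0)."""
    out = []
    for i, tpl in enumerate(repertoire):
        r, _ = render_rendition(
            tpl, DistortionSpec(delta=0.0, seed=seed + i), mode=mode,
            syllable_id=tpl.type_id, **kw,
        )
        out.append(r)
    return out


DEFAULT_GAP_MODEL = {
    "within_gap_median_s": 0.06,  # mean inter-syllable gap in juveniles ~60 ms
    "within_gap_log_sd": 0.5,
    "within_gap_max_s": 0.28,  # keep within-bout gaps below the 300 ms rule
    "bout_length_mean": 8.0,  # syllables per bout (geometric)
    "bout_gap_range_s": (6.0, 14.0),  # silence between bouts; allows baselines
    "session_start_s": 10.0,
}

SUBSONG_DURATION_MEAN_S = 0.12
PLASTIC_DURATION_CV = 0.10


def make_session(
    stage: float,
    n_syllables: int,
    repertoire: list[TutorTemplate],
    gap_model: dict | None = None,
    seed: int = 0,
    delta_dist=None,
    mode: str = "features",
    sample_rate: float = DEFAULT_SAMPLE_RATE,
) -> Session:
    """Simulate one singing session.

    ``stage`` interpolates the syllable-duration distribution between
    subsong (0: exponential, mean 0.12 s) and plastic song (1: peaked
    mixture of per-type Gaussians, cv 10%).  ``delta_dist(rng)`` draws each
    rendition's ground-truth distortion (default Uniform(0, 1)).
    """
    if n_syllables < 1:
        raise ValueError("n_syllables must be >= 1")
    if not 0.0 <= stage <= 1.0:
        raise ValueError("stage must lie in [0, 1]")
    if not repertoire:
        raise ValueError("empty repertoire")
    gm = dict(DEFAULT_GAP_MODEL)
    if gap_model:
        gm.update(gap_model)
    rng = np.random.default_rng(seed)
    if delta_dist is None:
        delta_dist = lambda r: r.uniform(0.0, 1.0)

    rows = []
    renditions = []
    t = float(gm["session_start_s"])
    in_bout = 0
    bout_len = max(1, int(rng.geometric(1.0 / gm["bout_length_mean"])))
    for i in range(n_syllables):
        tpl = repertoire[int(rng.integers(len(repertoire)))]
        delta = float(delta_dist(rng))
        if rng.uniform() < stage:
            dur = float(rng.normal(tpl.duration, PLASTIC_DURATION_CV * tpl.duration))
        else:
            dur = float(rng.exponential(SUBSONG_DURATION_MEAN_S))
        dur = float(np.clip(dur, 0.02, 1.0))
        sid = f"syl_{i:05d}"
        real, _ = render_rendition(
            tpl,
            DistortionSpec(delta=delta, seed=int(rng.integers(2**31))),
            mode=mode,
            sample_rate=sample_rate,
            syllable_id=sid,
            duration_override=dur,
        )
        rows.append(
            {
                "syllable_id": sid,
                "onset_s": t,
                "offset_s": t + dur,
                "true_type": tpl.type_id,
                "true_delta": delta,
            }
        )
        renditions.append(real)
        t += dur
        in_bout += 1
        if i == n_syllables - 1:
            break
        if in_bout >= bout_len:
            t += float(rng.uniform(*gm["bout_gap_range_s"]))
            in_bout = 0
            bout_len = max(1, int(rng.geometric(1.0 / gm["bout_length_mean"])))
        else:
            gap = float(
                np.exp(rng.normal(np.log(gm["within_gap_median_s"]),
                                  gm["within_gap_log_sd"]))
            )
            t += min(gap, gm["within_gap_max_s"])
    segments = pd.DataFrame(rows)
    return Session(
        segments=segments,
        renditions=renditions,
        stage=stage,
        mode=mode,
        total_duration=float(segments["offset_s"].iloc[-1] + gm["session_start_s"]),
    )


def _normalized_delta(deltas: np.ndarray) -> np.ndarray:
    dmax = float(np.max(deltas)) if deltas.size else 0.0
    if dmax <= 0:
        return np.zeros_like(deltas)
    return deltas / dmax


def simulate_neuron(
    profile: NeuronProfile,
    session: Session,
    delta_table: pd.DataFrame | None = None,
) -> np.ndarray:
    """Inhomogeneous-Poisson spike train for one unit over a session.

    Within each syllable the rate is
    ``baseline_rate * singing_gain * exp(beta * (1 - normalized delta) + eps)``
    with optional rendition-level lognormal noise ``eps`` whose sd is
    ``rate_noise_sd + variability_coupling * normalized delta``; a premotor
    ramp (if configured) adds rate in the lead window before each onset;
    bursts are inserted by turning single spikes into 4 ms doublets with
    probability ``burst_prob``.  Negative rates cannot arise (multiplicative
    model); an all-zero baseline yields an empty train.
    """
    if delta_table is None:
        delta_table = session.delta_table
    seg = session.segments
    rng = np.random.default_rng(profile.seed)
    T = session.total_duration
    if profile.baseline_rate == 0 and profile.premotor_ramp is None:
        return np.empty(0)

    deltas = delta_table.set_index("syllable_id").loc[
        seg["syllable_id"], "true_delta"
    ].to_numpy(dtype=float)
    nd = _normalized_delta(deltas)
    base_in = profile.baseline_rate * profile.singing_gain
    eps_sd = profile.rate_noise_sd + profile.variability_coupling * nd
    eps = rng.standard_normal(len(seg)) * eps_sd
    syl_rates = base_in * np.exp(profile.beta * (1.0 - nd) + eps)

    onsets = seg["onset_s"].to_numpy(float)
    offsets = seg["offset_s"].to_numpy(float)

    # Piecewise-constant rate: baseline outside syllables, syllable rate
    # inside, plus ramp amplitude in lead windows.
    edges = [0.0, T]
    edges.extend(onsets)
    edges.extend(offsets)
    ramp_amp = 0.0
    lead = 0.0
    if profile.premotor_ramp is not None:
        ramp_amp = float(profile.premotor_ramp["amplitude"])
        lead = float(profile.premotor_ramp.get("lead_ms", 50.0)) / 1000.0
        edges.extend(np.maximum(onsets - lead, 0.0))
    edges = np.unique(np.clip(np.asarray(edges, float), 0.0, T))

    mid = 0.5 * (edges[:-1] + edges[1:])
    idx = np.searchsorted(onsets, mid, side="right") - 1
    rate = np.full(mid.size, float(profile.baseline_rate))
    inside = (idx >= 0) & (mid < offsets[np.maximum(idx, 0)])
    rate[inside] = syl_rates[idx[inside]]
    if ramp_amp > 0 and lead > 0:
        nxt = np.minimum(np.searchsorted(onsets, mid, side="left"),
                         onsets.size - 1)
        in_lead = (mid < onsets[nxt]) & (mid >= onsets[nxt] - lead) & ~inside
        rate[in_lead] += ramp_amp

    lengths = np.diff(edges)
    counts = rng.poisson(rate * lengths)
    spikes = []
    for k in np.nonzero(counts)[0]:
        spikes.append(rng.uniform(edges[k], edges[k + 1], counts[k]))
    if not spikes:
        return np.empty(0)
    times = np.concatenate(spikes)

    if profile.burst_prob > 0 and times.size:
        dbl = rng.uniform(size=times.size) < profile.burst_prob
        times = np.concatenate([times, times[dbl] + BURST_DOUBLET_ISI_S])
    times = np.unique(np.sort(times))
    return times[times <= T]


def singing_annotations(session: Session, gap_threshold: float = 0.3) -> pd.DataFrame:
    """Annotation intervals (label ``song``) covering continuous singing."""
    from .spikes import segment_episodes

    eps = segment_episodes(session.segments, gap_threshold=gap_threshold)
    return pd.DataFrame(
        {
            "onset_s": [e.onset for e in eps],
            "offset_s": [e.offset for e in eps],
            "label": "song",
        }
    )


def write_bundle(
    path: str | Path,
    session: Session,
    spikes: dict[str, np.ndarray],
    profiles: dict[str, NeuronProfile] | None = None,
    seed: int | None = None,
    write_audio: bool = False,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
) -> Path:
    """Write a session bundle: segments.csv, spikes_<id>.csv, truth.json.

    With ``write_audio`` and a waveform-mode session, renders ``audio.wav``
    (16-bit PCM) by placing each rendition at its segment onset.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    session.segments.to_csv(path / "segments.csv", index=False)
    for name, times in spikes.items():
        pd.DataFrame({"spike_time_s": times}).to_csv(
            path / f"spikes_{name}.csv", index=False
        )
    truth = {
        "stage": session.stage,
        "mode": session.mode,
        "seed": seed,
        "profiles": {k: asdict(v) for k, v in (profiles or {}).items()},
    }
    (path / "truth.json").write_text(json.dumps(truth, indent=2))
    if write_audio and session.mode == "waveform":
        n = int(np.ceil(session.total_duration * sample_rate))
        audio = np.zeros(n)
        for (_, row), (wav, sr) in zip(session.segments.iterrows(), session.renditions):
            i0 = int(round(row["onset_s"] * sample_rate))
            audio[i0 : i0 + wav.size] += wav[: max(0, n - i0)]
        peak = np.max(np.abs(audio))
        if peak > 0:
            audio = 0.9 * audio / peak
        wavfile.write(path / "audio.wav", sample_rate,
                      (audio * 32767).astype(np.int16))
    return path
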