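"""End-to-end orchestration: one configuration, stable on-disk contracts.

Runs simulate -> features -> cluster -> tutor-sim -> neural -> stats ->
develop on a session bundle and writes CSV/JSON outputs plus a manifest.
All times are seconds from session start; intervals are half-open
``[onset, offset)``; CSV with a header row is the interchange dialect.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import development, population, similarity, spikes, synth
from .features import (
    DEFAULT_OVERLAP_S,
    DEFAULT_WINDOW_S,
    FeatureTrack,
    compute_feature_tracks,
    compute_spectrogram,
    summary_table,
)
from .similarity import UNCLASSIFIED

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All tunable parameters of the pipeline, with the standard defaults."""

    # simulation
    seed: int = 0
    n_tutor_types: int = 4
    n_syllables: int = 300
    stage: float = 0.5
    n_neurons: int = 4
    mode: str = "features"  # "features" (fast) or "waveform" (end-to-end)
    neuron_profiles: list[dict] = field(default_factory=list)
    # acoustic features
    window_s: float = DEFAULT_WINDOW_S
    overlap_s: float = DEFAULT_OVERLAP_S
    # distances / clustering
    warp_penalty: float = similarity.DEFAULT_WARP_PENALTY
    k: int = 4
    k_range: tuple[int, int] = similarity.DEFAULT_K_RANGE
    max_scatter: float | None = None
    merge: list[list[str]] = field(default_factory=list)
    # neural analysis
    gap_threshold_s: float = spikes.GAP_THRESHOLD_S
    baseline_min_s: float = spikes.BASELINE_MIN_LEN_S
    baseline_guard_s: float = spikes.BASELINE_GUARD_S
    pre_window_s: float = spikes.PRE_WINDOW_S
    burst_isi_s: float = spikes.BURST_ISI_S
    min_renditions: int = spikes.MIN_RENDITIONS
    n_perm: int = population.N_PERMUTATIONS
    n_perm_repeats: int = population.N_PERMUTATION_REPEATS

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        cfg = cls(**data)
        if isinstance(cfg.k_range, list):
            cfg.k_range = tuple(cfg.k_range)
        return cfg

    def to_file(self, path: str | Path) -> None:
        data = asdict(self)
        data["k_range"] = list(self.k_range)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def _default_profiles(cfg: RunConfig) -> list[synth.NeuronProfile]:
    if cfg.neuron_profiles:
        return [synth.NeuronProfile(**p) for p in cfg.neuron_profiles]
    rng = np.random.default_rng(cfg.seed + 1)
    out = []
    for i in range(cfg.n_neurons):
        out.append(
            synth.NeuronProfile(
                baseline_rate=6.0,
                singing_gain=2.0 if i % 2 == 0 else 0.5,
                beta=0.5 if i % 2 == 0 else -0.5,
                burst_prob=0.2,
                seed=int(rng.integers(2**31)),
            )
        )
    return out


def _tracks_for_session(session: synth.Session, cfg: RunConfig) -> list[FeatureTrack]:
    """Feature tracks for every rendition (extracting from audio if needed)."""
    if session.mode == "features":
        return list(session.renditions)
    tracks = []
    for (_, row), (wav, sr) in zip(session.segments.iterrows(), session.renditions):
        spec = compute_spectrogram(wav, sr, cfg.window_s, cfg.overlap_s)
        tracks.append(
            compute_feature_tracks(spec, syllable_id=row["syllable_id"])
        )
    return tracks


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute the full synthetic-session analysis; returns the run directory.

    Stage failures raise with the stage name attached; outputs written so
    far are preserved.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": []}

    def _stage(name):
        manifest["stages"].append(name)
        log.info("stage: %s", name)

    try:
        _stage("simulate")
        repertoire = synth.make_tutor_repertoire(config.n_tutor_types,
                                                 seed=config.seed)
        session = synth.make_session(
            stage=config.stage,
            n_syllables=config.n_syllables,
            repertoire=repertoire,
            seed=config.seed + 2,
            mode=config.mode,
        )
        profiles = _default_profiles(config)
        spike_trains = {
            f"neuron_{i}": synth.simulate_neuron(p, session)
            for i, p in enumerate(profiles)
        }
        synth.write_bundle(out / "bundle", session, spike_trains,
                           profiles={f"neuron_{i}": p
                                     for i, p in enumerate(profiles)},
                           seed=config.seed)

        _stage("features")
        tutor_tracks = synth.render_tutor_set(repertoire, mode="features")
        juv_tracks = _tracks_for_session(session, config)
        all_tracks = tutor_tracks + juv_tracks
        vectors = summary_table(all_tracks)

        _stage("cluster")
        dmat = similarity.combined_distance(vectors, all_tracks,
                                            config.warp_penalty)
        tutor_ids = [t.type_id for t in repertoire]
        juv_ids = list(session.segments["syllable_id"])
        juv_idx = [dmat.ids.index(j) for j in juv_ids]
        juv_d = similarity.DistanceMatrix(
            dmat.values[np.ix_(juv_idx, juv_idx)], juv_ids,
            "dissimilarity_index",
        )
        assignment = similarity.cluster_syllables(
            juv_d, k=config.k, k_range=config.k_range,
            max_scatter=config.max_scatter,
            merge=config.merge or None, enforce_k_range=False,
        )
        proto = similarity.prototypicality(juv_d, assignment)
        types_df = pd.DataFrame(
            {"syllable_id": juv_ids,
             "type": assignment.labels.values,
             "prototypicality": proto.values}
        )
        types_df.to_csv(out / "types.csv", index=False)

        _stage("tutor-sim")
        sim_df = similarity.tutor_similarity(dmat, juv_ids, tutor_ids)
        classified = types_df[types_df["type"] != UNCLASSIFIED]["syllable_id"]
        sim_cls = sim_df[sim_df["syllable_id"].isin(classified)]
        split = similarity.median_split(
            sim_cls.set_index("syllable_id")["tutor_similarity"],
            min_n=min(config.min_renditions, max(2, len(sim_cls))),
        )
        sim_df = sim_df.merge(split.rename("split"), left_on="syllable_id",
                              right_index=True, how="left")
        sim_df.to_csv(out / "tutor_similarity.csv", index=False)

        _stage("neural")
        episodes = spikes.segment_episodes(session.segments,
                                           config.gap_threshold_s)
        annotations = synth.singing_annotations(session,
                                                config.gap_threshold_s)
        baselines = spikes.find_baselines(
            annotations, (0.0, session.total_duration),
            config.baseline_min_s, config.baseline_guard_s,
        )
        neuron_rows = []
        rendition_frames = []
        neuron_sim_rows = []
        assoc_rows = []
        for name, train in spike_trains.items():
            s, b = spikes.episode_baseline_rates(train, episodes, baselines)
            rs = spikes.response_strength(s, b) if s.size >= 2 else np.nan
            stat, p, flag = (spikes.responsiveness_test(s, b)
                             if s.size >= 2 and b.size >= 2
                             else (np.nan, np.nan, "ns"))
            bf_sing = spikes.burst_fraction(
                train, [(e.onset, e.offset) for e in episodes],
                config.burst_isi_s)
            bf_base = spikes.burst_fraction(
                train, [(x.onset, x.offset) for x in baselines],
                config.burst_isi_s)
            rates = spikes.rendition_rate_table(
                train, session.segments, episodes, baselines,
                config.pre_window_s)
            rates["neuron"] = name
            rendition_frames.append(rates)
            merged = rates.merge(sim_df, on="syllable_id")
            type_rates = (
                rates.merge(types_df, on="syllable_id")
                .query("type != @UNCLASSIFIED")
                .groupby("type")["rate"].mean()
            )
            af = (spikes.activity_fraction(type_rates.to_numpy())
                  if len(type_rates) >= 2 and type_rates.sum() > 0 else np.nan)
            neuron_rows.append(
                {"neuron": name, "response_strength": rs,
                 "responsiveness_p": p, "flag": flag,
                 "burst_fraction_singing": bf_sing,
                 "burst_fraction_baseline": bf_base,
                 "activity_fraction": af}
            )
            if len(merged) >= 2:
                reg = population.similarity_regression(
                    merged["baseline_corrected_rate"].to_numpy(),
                    merged["tutor_similarity"].to_numpy(),
                    min_n=2)
                pct, sig = population.permutation_significance(
                    merged["baseline_corrected_rate"].to_numpy(),
                    merged["tutor_similarity"].to_numpy(),
                    n_perm=config.n_perm, seed=config.seed + 7, min_n=2)
                neuron_sim_rows.append(
                    {"neuron": name, "r": reg.r,
                     "slope_sign": int(np.sign(reg.slope)),
                     "percentile": pct, "significant": sig}
                )
                assoc_rows.append(pd.DataFrame(
                    {"neuron": name,
                     "rate": merged["baseline_corrected_rate"],
                     "similarity": merged["tutor_similarity"]}
                ))
        pd.DataFrame(neuron_rows).to_csv(out / "neuron_stats.csv", index=False)
        pd.concat(rendition_frames).to_csv(out / "rendition_rates.csv",
                                           index=False)
        pd.DataFrame(neuron_sim_rows).to_csv(out / "neuron_similarity.csv",
                                             index=False)

        _stage("stats")
        summary: dict = {}
        if len(assoc_rows) >= 2:
            table = pd.concat(assoc_rows)
            try:
                summary["population_association"] = population.population_association(
                    table, min_neurons=min(5, len(assoc_rows)),
                    min_n=min(config.min_renditions, 2))
            except ValueError as exc:
                summary["population_association"] = {"error": str(exc)}
        onsets = session.segments["onset_s"].to_numpy()
        psth_neurons = [(train, onsets) for train in spike_trains.values()]
        if len(psth_neurons) >= 2:
            h = population.population_psth(psth_neurons)
            mask = population.psth_significance(h)
            pd.DataFrame(
                {"bin_center_ms": h.bin_centers_ms, "mean": h.mean,
                 "sem": h.sem, "significant": mask}
            ).to_csv(out / "psth.csv", index=False)
            summary["psth_significant_fraction"] = float(mask.mean())
        (out / "population_summary.json").write_text(
            json.dumps(summary, indent=2, default=float))

        _stage("develop")
        durations = (session.segments["offset_s"]
                     - session.segments["onset_s"]).to_numpy()
        dev = development.exponential_gof(
            durations, session_id="synthetic",
            min_n=min(100, len(durations)))
        pd.DataFrame([asdict(dev)]).rename(
            columns={"session_id": "session", "n_syllables": "n"}
        ).to_csv(out / "development.csv", index=False)
    except Exception as exc:
        stage = manifest["stages"][-1] if manifest["stages"] else "setup"
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest["input_hash"] = hashlib.sha256(
        json.dumps(asdict(config), sort_keys=True, default=str).encode()
    ).hexdigest()
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str))
    return out


def validate_inputs(bundle_dir: str | Path) -> list[str]:
    """Check a session bundle for structural problems; returns violations."""
    bundle = Path(bundle_dir)
    violations: list[str] = []
    seg_path = bundle / "segments.csv"
    if not seg_path.exists():
        return [f"missing {seg_path.name}"]
    seg = pd.read_csv(seg_path)
    on = seg["onset_s"].to_numpy(float)
    off = seg["offset_s"].to_numpy(float)
    if np.any(off <= on):
        violations.append("segment offsets not greater than onsets")
    order = np.argsort(on)
    if np.any(on[order][1:] < off[order][:-1]):
        violations.append("overlapping segments")
    end = float(off.max()) if off.size else 0.0
    audio = bundle / "audio.wav"
    if audio.exists():
        try:
            from scipy.io import wavfile

            sr, data = wavfile.read(audio)
            audio_end = data.shape[0] / sr
            if end > audio_end + 1e-6:
                violations.append("segments extend beyond audio")
            end = max(end, audio_end)
        except Exception as exc:
            violations.append(f"unreadable audio.wav: {exc}")
    for spk in sorted(bundle.glob("spikes_*.csv")):
        times = pd.read_csv(spk)["spike_time_s"].to_numpy(float)
        if np.any(np.diff(times) < 0):
            violations.append(f"{spk.name}: spike times not sorted")
        if times.size and times.max() > end + 60.0:
            violations.append(f"{spk.name}: spike time beyond recording span")
    return violations
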