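"""End-to-end experiment orchestration.

Two-phase flow on a synthetic recording campaign: simulate the dataset,
segment each recording into its activity sample, hold out the falls, and then
(phase 1) discover the normal-activity clusters with per-sequence HMMs +
symmetrized-KL distances + self-tuning spectral clustering, and (phase 2)
fit one HMM per cluster, form log-likelihood feature vectors, and train the
one-class SVM profile.  The held-out normals and all falls form the test mix;
both the clustered detector and the single-HMM baseline are scored and
evaluated by ROC/AUC.  Everything is reproducible from (config, seed): the
global seed fans out to per-stage seeds through a fixed SeedSequence rule.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import yaml

from . import anomaly, distances, evaluation, segmentation, sensing, spectral

__all__ = [
    "HMMSettings",
    "OSVMSettings",
    "SegmentationSettings",
    "ExperimentSettings",
    "PipelineConfig",
    "stage_seed",
    "extract_samples",
    "run_experiment",
]

#: fixed stage indices of the seed-splitting rule
_STAGES = {"simulate": 0, "split": 1, "sequence_models": 2,
           "cluster_models": 3, "onehmm": 4}


@dataclass(frozen=True)
class HMMSettings:
    """HMM sizes and EM schedule.

    The profiling models (one per discovered cluster, and the single-HMM
    baseline) use ``n_states``/``n_mix`` — 8 states, 2 Gaussians.  The
    per-sequence models that build the likelihood-space embedding use the
    much smaller ``embed_n_states``/``embed_n_mix``: embedding models must
    generalize across sequences for the normalized likelihood columns to
    share support (large per-sequence models memorize their own segment and
    the distance geometry collapses).  ``covar_floor`` is in squared ADC code
    units; 1.0 matches the quantization/sensor noise floor of the streams.
    """

    n_states: int = 8
    n_mix: int = 2
    embed_n_states: int = 3
    embed_n_mix: int = 1
    max_iter: int = 20
    tol: float = 1e-3
    covar_floor: float = 1.0


@dataclass(frozen=True)
class OSVMSettings:
    nu: float = 0.01
    gamma: str | float = "median"
    log_compress: bool = False


@dataclass(frozen=True)
class SegmentationSettings:
    window_s: float = segmentation.DEFAULT_WINDOW_S
    hop_s: float = segmentation.DEFAULT_HOP_S
    hangover_s: float = segmentation.DEFAULT_HANGOVER_S
    min_duration_s: float = segmentation.DEFAULT_MIN_DURATION_S
    threshold: float | None = None


@dataclass(frozen=True)
class ExperimentSettings:
    """Campaign shape: 8 subjects x 5 activities x 10 reps; 240 normal train."""

    n_subjects: int = 8
    activities: tuple[str, ...] = sensing.ACTIVITIES
    reps_per_activity: int = 10
    train_size: int = 240
    noise_sd: float = 0.02


@dataclass(frozen=True)
class PipelineConfig:
    sensing: sensing.PartitionConfig = field(default_factory=sensing.PartitionConfig)
    segmentation: SegmentationSettings = field(default_factory=SegmentationSettings)
    hmm: HMMSettings = field(default_factory=HMMSettings)
    spectral: spectral.SpectralConfig = field(default_factory=spectral.SpectralConfig)
    osvm: OSVMSettings = field(default_factory=OSVMSettings)
    experiment: ExperimentSettings = field(default_factory=ExperimentSettings)
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        def sub(key, klass):
            v = d.get(key, {})
            if key == "experiment" and "activities" in v:
                v = dict(v, activities=tuple(v["activities"]))
            if key == "sensing" and "ring_radii" in v:
                v = dict(v, ring_radii=tuple(v["ring_radii"]))
            return klass(**v)
        return cls(
            sensing=sub("sensing", sensing.PartitionConfig),
            segmentation=sub("segmentation", SegmentationSettings),
            hmm=sub("hmm", HMMSettings),
            spectral=sub("spectral", spectral.SpectralConfig),
            osvm=sub("osvm", OSVMSettings),
            experiment=sub("experiment", ExperimentSettings),
            seed=int(d.get("seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: SeedSequence((global_seed, stage_index))."""
    ss = np.random.SeedSequence((int(global_seed), _STAGES[stage]))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def extract_samples(streams, seg_cfg: SegmentationSettings):
    """One activity sample per recording: the highest-energy detected segment.

    Each synthetic recording emulates exactly one activity repetition, so the
    STE detector's highest-energy segment is taken as the sample; a recording
    with no supra-threshold activity falls back to the whole stream.
    """
    samples = []
    for stream in streams:
        fs = stream.sampling_rate
        win = max(int(round(seg_cfg.window_s * fs)), 1)
        hop = max(int(round(seg_cfg.hop_s * fs)), 1)
        energy = segmentation.short_time_energy(stream, win, hop)
        segs = segmentation.detect_segments(
            energy, threshold=seg_cfg.threshold,
            min_duration_s=seg_cfg.min_duration_s,
            hangover_s=seg_cfg.hangover_s, sampling_rate=fs)
        if not segs:
            samples.append(stream)
            continue
        def seg_energy(seg):
            v = stream.values[:, seg.start:min(seg.end, stream.n_samples)]
            return float((v.astype(float) ** 2).sum())
        best = max(segs, key=seg_energy)
        samples.append(segmentation.extract_segments(stream, [best])[0])
    return samples


def run_experiment(config: PipelineConfig | None = None, outdir=None) -> dict:
    """Run the full synthetic experiment; returns the results report dict.

    Training uses only normal samples (the runner drops falls from the train
    pool itself — the premise of profiling normal activity without labels);
    no stage other than simulation and final evaluation reads activity labels.
    If ``outdir`` is given, the report, run manifest and per-stage artifacts
    are written there.
    """
    if config is None:
        config = PipelineConfig()
    exp = config.experiment
    hmm_kw = dict(n_states=config.hmm.n_states, n_mix=config.hmm.n_mix,
                  max_iter=config.hmm.max_iter, tol=config.hmm.tol,
                  covar_floor=config.hmm.covar_floor)
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    streams = sensing.generate_dataset(
        n_subjects=exp.n_subjects, activities=exp.activities,
        reps_per_activity=exp.reps_per_activity,
        seed=stage_seed(config.seed, "simulate"),
        config=config.sensing, noise_sd=exp.noise_sd)
    timings["simulate"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    samples = extract_samples(streams, config.segmentation)
    timings["segment"] = time.perf_counter() - t0

    is_abnormal = np.array(
        [s.metadata["activity"] == sensing.ABNORMAL_ACTIVITY for s in samples])
    normal_idx = np.flatnonzero(~is_abnormal)
    abnormal_idx = np.flatnonzero(is_abnormal)
    if exp.train_size > len(normal_idx):
        raise ValueError(
            f"train_size={exp.train_size} exceeds the {len(normal_idx)} "
            "available normal samples")
    rng = np.random.default_rng(stage_seed(config.seed, "split"))
    perm = rng.permutation(normal_idx)
    train_idx = np.sort(perm[:exp.train_size])
    test_idx = np.concatenate([perm[exp.train_size:], abnormal_idx])
    test_idx = test_idx[rng.permutation(len(test_idx))]

    train_seqs = [samples[i].values.astype(float) for i in train_idx]
    test_seqs = [samples[i].values.astype(float) for i in test_idx]
    test_abnormal = is_abnormal[test_idx]

    # phase 1: unsupervised structure discovery on the training pool
    t0 = time.perf_counter()
    embed_kw = dict(hmm_kw, n_states=config.hmm.embed_n_states,
                    n_mix=config.hmm.embed_n_mix)
    seq_models = distances.fit_sequence_models(
        train_seqs, seed=stage_seed(config.seed, "sequence_models"), **embed_kw)
    l = distances.likelihood_matrix(train_seqs, seq_models)
    d = distances.distance_matrix(distances.normalize_columns(l))
    timings["distances"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    solution = spectral.cluster_distances(d, config.spectral)
    timings["cluster"] = time.perf_counter() - t0

    # phase 2: cluster HMMs -> feature vectors -> one-class SVM
    t0 = time.perf_counter()
    cluster_models = anomaly.fit_cluster_models(
        train_seqs, solution.labels,
        seed=stage_seed(config.seed, "cluster_models"), **hmm_kw)
    feats_train = anomaly.extract_features(train_seqs, cluster_models)
    osvm = anomaly.train_osvm(feats_train, nu=config.osvm.nu,
                              gamma=config.osvm.gamma,
                              log_compress=config.osvm.log_compress)
    feats_test = anomaly.extract_features(test_seqs, cluster_models)
    scores_osvm = anomaly.decision_score(feats_test, osvm)
    timings["profile"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    scores_onehmm = anomaly.onehmm_baseline(
        train_seqs, test_seqs, seed=stage_seed(config.seed, "onehmm"), **hmm_kw)
    timings["onehmm"] = time.perf_counter() - t0

    roc_osvm = evaluation.roc_auc(scores_osvm, test_abnormal)
    roc_onehmm = evaluation.roc_auc(scores_onehmm, test_abnormal)

    report = {
        "config": config.to_dict(),
        "seed": config.seed,
        "n_streams": len(streams),
        "n_samples": len(samples),
        "n_train": len(train_idx),
        "n_test": len(test_idx),
        "n_test_abnormal": int(test_abnormal.sum()),
        "c_best": int(solution.c_best),
        "alignment_costs": {str(c): float(j) for c, j in solution.costs.items()},
        "auc_sc_osvm": roc_osvm.auc,
        "auc_onehmm": roc_onehmm.auc,
    }
    if outdir is not None:
        from . import io as _io
        import pathlib
        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        _io.write_matrix_tsv(outdir / "distances.tsv", d)
        _io.write_labels_tsv(outdir / "labels.tsv", solution.labels)
        manifest = {
            "config": config.to_dict(), "seed": config.seed,
            "artifacts": ["report.json", "distances.tsv", "labels.tsv"],
            "timings_s": {k: round(v, 3) for k, v in timings.items()},
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    report["timings_s"] = timings
    return report
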