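"""End-to-end identification pipeline and the synthetic-cohort experiment.

Wires the stages together: wavelet denoising -> R-peak detection ->
R-R-R segmentation/standardization -> KSVD dictionary learning -> OMP
encoding + max-abs pooling -> enrollment -> bundle-search evaluation.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import identify, preprocess, rpeak, segment, sparse, synth
from .records import EcgRecord

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunable pipeline parameters with their defaults.

    Dictionary defaults (1000 atoms, sparsity 10, 300 iterations,
    tolerance 1e-6) and segment defaults (length 400, expansion 20,
    groups of 3, 30 enrolled matrices per subject) are the method's
    operating point; experiments may override them.
    """

    # preprocess
    wavelet: str = "db4"
    levels: int = 8
    drop_bands: tuple[str, ...] = ("d1", "a8")
    threshold_rule: str = "universal"  # universal | none
    # rpeak
    bandpass_low: float = 5.0
    bandpass_high: float = 15.0
    integration_window: float = 0.15
    refractory: float = 0.2
    square: bool = True
    detect_on_denoised: bool = True
    # segment
    segment_length: int = 400
    expand: int = 20
    stride: int = 1
    group_size: int = 3
    group_mode: str = "consecutive"  # consecutive | thirds
    # sparse
    atoms: int = 1000
    sparsity: int = 10
    iterations: int = 300
    tol: float = 1e-6
    max_train_segments: int = 2500
    # identify
    per_subject: int = 30
    weight_rule: str = "uniform"
    reject_mode: str = "mean"
    decision_rule: str = "distance"  # distance | votes
    threshold_percentile: float = 99.0

    def detector(self) -> rpeak.DetectorConfig:
        return rpeak.DetectorConfig(
            bandpass_low=self.bandpass_low,
            bandpass_high=self.bandpass_high,
            integration_window=self.integration_window,
            refractory=self.refractory,
            square=self.square,
        )

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["drop_bands"] = list(self.drop_bands)
        Path(path).write_text(yaml.safe_dump(data))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        if "drop_bands" in data:
            data["drop_bands"] = tuple(data["drop_bands"])
        return cls(**data)


def process_record(
    rec: EcgRecord, cfg: PipelineConfig | None = None
) -> tuple[EcgRecord, rpeak.RPeakList, list[np.ndarray]]:
    """Denoise, detect R peaks and extract standardized segment vectors."""
    cfg = cfg or PipelineConfig()
    clean = preprocess.denoise_record(
        rec,
        levels=cfg.levels,
        wavelet=cfg.wavelet,
        drop_bands=set(cfg.drop_bands),
        lam_rule=cfg.threshold_rule,
    )
    target = clean if cfg.detect_on_denoised else rec
    peaks = rpeak.detect_rpeaks(target, cfg.detector())
    if len(peaks) < 3:
        return clean, peaks, []
    if cfg.group_mode == "thirds":
        windows = segment.make_rrr_windows(clean, peaks, cfg.expand, cfg.stride)
        vectors = []
        for w in windows:
            cols = segment.split_window_thirds(clean, w, cfg.segment_length)
            vectors.extend(cols.T)
        return clean, peaks, vectors
    vectors, _ = segment.segment_record(
        clean, peaks, D=cfg.segment_length, expand=cfg.expand, stride=cfg.stride
    )
    return clean, peaks, vectors


def features_from_vectors(
    vectors: list[np.ndarray],
    dictionary: sparse.SparseDictionary,
    cfg: PipelineConfig,
    subject_id: str = "",
    max_groups: int | None = None,
) -> list[sparse.FeatureVector]:
    """Group standardized vectors, encode each group, pool to features."""
    matrices = segment.group_segments(vectors, cfg.group_size, subject_id)
    if max_groups is not None:
        matrices = matrices[:max_groups]
    out = []
    for mat in matrices:
        code = sparse.encode_matrix(dictionary, mat, cfg.sparsity, cfg.tol)
        out.append(sparse.max_pool(code, subject_id=subject_id))
    return out


def run_identification_experiment(
    n_subjects: int = 20,
    seed: int = 0,
    cfg: PipelineConfig | None = None,
    train_duration: float = 300.0,
    test_duration: float = 110.0,
    n_enroll: int = 30,
    n_test: int = 30,
    fs: float = 250.0,
    with_shuffled_control: bool = False,
) -> dict:
    """Full synthetic-cohort identification experiment.

    Generates one training and one disjoint test recording per subject,
    trains a shared KSVD dictionary on pooled training segments (capped
    at ``cfg.max_train_segments`` seeded-subsampled columns), enrolls
    ``n_enroll`` pooled feature vectors per subject, and evaluates
    rank-1 recognition on ``n_test`` test feature vectors per subject.
    Optionally repeats the evaluation with enrollment labels randomly
    shuffled as a chance-level control.
    """
    cfg = cfg or PipelineConfig()
    base = seed % (2**31 - 100_000)
    cohort = synth.make_cohort(n_subjects, seed=base)

    train_vectors: dict[str, list[np.ndarray]] = {}
    test_vectors: dict[str, list[np.ndarray]] = {}
    for i, morph in enumerate(cohort):
        sid = f"S{i:03d}"
        rec_tr, _ = synth.synthesize_ecg(
            morph, train_duration, fs, seed=base + 10 + i, subject_id=sid
        )
        rec_te, _ = synth.synthesize_ecg(
            morph, test_duration, fs, seed=base + 50_000 + i, subject_id=sid
        )
        _, _, vec_tr = process_record(rec_tr, cfg)
        _, _, vec_te = process_record(rec_te, cfg)
        train_vectors[sid] = vec_tr
        test_vectors[sid] = vec_te
        logger.info("subject %s: %d train / %d test segments", sid, len(vec_tr), len(vec_te))

    pooled = [v for vecs in train_vectors.values() for v in vecs]
    Y = np.column_stack(pooled)
    rng = np.random.default_rng(base + 999)
    if Y.shape[1] > cfg.max_train_segments:
        keep = rng.choice(Y.shape[1], cfg.max_train_segments, replace=False)
        Y = Y[:, np.sort(keep)]

    dictionary, _ = sparse.ksvd_train(
        Y, K=cfg.atoms, T0=cfg.sparsity, iters=cfg.iterations, tol=cfg.tol, seed=base + 7
    )

    enroll_feats = []
    test_feats = []
    for sid in train_vectors:
        enroll_feats.extend(
            features_from_vectors(train_vectors[sid], dictionary, cfg, sid, n_enroll)
        )
        for fv in features_from_vectors(test_vectors[sid], dictionary, cfg, sid, n_test):
            test_feats.append((fv, sid))

    S = identify.enroll(
        enroll_feats,
        per_subject=n_enroll,
        threshold_percentile=cfg.threshold_percentile,
    )
    metrics = identify.evaluate_identification(
        test_feats, S, weight_rule=cfg.weight_rule, reject_mode=cfg.reject_mode,
        decision_rule=cfg.decision_rule,
    )
    results = {
        "n_subjects": n_subjects,
        "n_queries": metrics.n_queries,
        "recognition_rate": metrics.recognition_rate,
        "rejection_rate": metrics.rejection_rate,
        "R_t": S.R_t,
        "dictionary_meta": dictionary.training_meta,
        "standard_set": S,
        "metrics": metrics,
    }

    if with_shuffled_control:
        shuffled_labels = list(S.labels)
        rng.shuffle(shuffled_labels)
        S_shuffled = identify.StandardSet(
            features=S.features.copy(),
            labels=shuffled_labels,
            R_t=S.R_t,
            per_subject=S.per_subject,
        )
        control = identify.evaluate_identification(
            test_feats, S_shuffled, weight_rule=cfg.weight_rule,
            reject_mode=cfg.reject_mode, decision_rule=cfg.decision_rule,
        )
        results["shuffled_recognition_rate"] = control.recognition_rate

    return results
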