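#!/usr/bin/env python
"""Optional replication on the European ST-T database.

This script is separate from the desk-scale acceptance run: it requires a
local copy of the European ST-T WFDB records (two-channel, 250 Hz,
format 212), which are not distributed with this package. Point
``--data-dir`` at a directory containing ``*.hea``/``*.dat`` pairs.

Per subject it uses ~80,000 samples (about 5 min) for dictionary training
and enrollment and the following ~40,000 samples for test queries,
mirroring the published protocol (30 enrolled and 30 test feature
windows per subject).

Usage:
    python scripts/replicate_stt.py --data-dir /path/to/stt \
        --n-subjects 20 --lead MLII --out results/stt.json
"""

from __future__ import annotations

import argparse
import json
import warnings
from pathlib import Path

import numpy as np

from ecgid import EcgRecord, enroll, evaluate_identification, read_wfdb_record
from ecgid.pipeline import PipelineConfig, features_from_vectors, process_record
from ecgid.sparse import ksvd_train


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data-dir", type=str, required=True)
    parser.add_argument("--n-subjects", type=int, default=20)
    parser.add_argument("--lead", type=str, default="MLII")
    parser.add_argument("--train-samples", type=int, default=80_000)
    parser.add_argument("--test-samples", type=int, default=40_000)
    parser.add_argument("--atoms", type=int, default=1000)
    parser.add_argument("--iterations", type=int, default=300)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=str, default=None)
    args = parser.parse_args()

    cfg = PipelineConfig(atoms=args.atoms, iterations=args.iterations)
    headers = sorted(Path(args.data_dir).glob("*.hea"))[: args.n_subjects]
    if len(headers) < args.n_subjects:
        raise SystemExit(
            f"found only {len(headers)} records in {args.data_dir}; "
            f"need {args.n_subjects}"
        )

    train_vecs, test_vecs = {}, {}
    for hea in headers:
        rec = read_wfdb_record(hea.with_suffix(""), args.lead)
        sid = rec.subject_id
        tr = EcgRecord(rec.samples[: args.train_samples], rec.fs, sid, rec.lead)
        te = EcgRecord(
            rec.samples[args.train_samples : args.train_samples + args.test_samples],
            rec.fs, sid, rec.lead,
        )
        _, _, train_vecs[sid] = process_record(tr, cfg)
        _, _, test_vecs[sid] = process_record(te, cfg)
        print(f"{sid}: {len(train_vecs[sid])} train / {len(test_vecs[sid])} test segments")

    Y = np.column_stack([v for vs in train_vecs.values() for v in vs])
    rng = np.random.default_rng(args.seed)
    if Y.shape[1] > cfg.max_train_segments:
        keep = rng.choice(Y.shape[1], cfg.max_train_segments, replace=False)
        Y = Y[:, np.sort(keep)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        dictionary, _ = ksvd_train(
            Y, K=cfg.atoms, T0=cfg.sparsity, iters=cfg.iterations, tol=cfg.tol,
            seed=args.seed,
        )

    enroll_feats, test_feats = [], []
    for sid in train_vecs:
        enroll_feats += features_from_vectors(train_vecs[sid], dictionary, cfg, sid, 30)
        test_feats += [
            (fv, sid)
            for fv in features_from_vectors(test_vecs[sid], dictionary, cfg, sid, 30)
        ]
    S = enroll(enroll_feats, per_subject=30, threshold_percentile=cfg.threshold_percentile)
    metrics = evaluate_identification(
        test_feats, S, cfg.weight_rule, cfg.reject_mode, cfg.decision_rule
    )
    payload = {
        "n_subjects": len(train_vecs),
        "n_queries": metrics.n_queries,
        "recognition_rate_percent": 100.0 * metrics.recognition_rate,
        "rejection_rate_percent": 100.0 * metrics.rejection_rate,
    }
    print(json.dumps(payload, indent=2))
    if args.out:
        Path(args.out).parent.mkdir(parents=True, exist_ok=True)
        Path(args.out).write_text(json.dumps(payload, indent=2))


if __name__ == "__main__":
    main()
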