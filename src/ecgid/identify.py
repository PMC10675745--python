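"""Enrollment and the co-dimensional bundle-search classifier.

Each enrolled subject contributes a set of pooled feature vectors (the
standard set). To identify a query, every nonzero coordinate of its
feature vector looks up the nearest enrolled entry at that same
coordinate (absolute difference) and votes for that entry's subject; the
top-voted subject wins, and the query is rejected as unknown when its
mean matched distance exceeds the threshold R_t (open-set rejection).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .sparse import FeatureVector

logger = logging.getLogger(__name__)

REJECT = "REJECT"


@dataclass
class StandardSet:
    """Gallery of enrolled feature vectors with an open-set threshold."""

    features: np.ndarray  # (M, K)
    labels: list[str]
    R_t: float
    per_subject: int = 30

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2 or self.features.shape[0] != len(self.labels):
            raise ValueError("features must be (M, K) matching labels")
        if not (self.R_t > 0):
            raise ValueError("rejection threshold R_t must be positive")

    @property
    def K(self) -> int:
        return self.features.shape[1]

    @property
    def M(self) -> int:
        return self.features.shape[0]

    @property
    def subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for lb in self.labels:
            seen.setdefault(lb, None)
        return list(seen)

    def subject_rows(self, label: str) -> np.ndarray:
        """Row indices of one subject's enrolled entries (cached)."""
        cache = getattr(self, "_rows_cache", None)
        if cache is None:
            cache = {}
            for i, lb in enumerate(self.labels):
                cache.setdefault(lb, []).append(i)
            cache = {k: np.asarray(v) for k, v in cache.items()}
            object.__setattr__(self, "_rows_cache", cache)
        return cache[label]

    def save(self, path: str | Path) -> None:
        payload = {
            "version": 1,
            "R_t": self.R_t,
            "per_subject": self.per_subject,
            "labels": self.labels,
            "features": self.features.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "StandardSet":
        payload = json.loads(Path(path).read_text())
        return cls(
            features=np.asarray(payload["features"], dtype=float),
            labels=list(payload["labels"]),
            R_t=float(payload["R_t"]),
            per_subject=int(payload.get("per_subject", 30)),
        )


@dataclass
class IdentificationResult:
    predicted: str  # subject label or REJECT
    votes: dict[str, float]
    mean_distance: float
    threshold: float
    best_label: str  # top-voted label even when rejected


def enroll(
    features: list[tuple[FeatureVector, str]] | list[FeatureVector],
    per_subject: int = 30,
    R_t: float | None = None,
    threshold_percentile: float = 99.0,
) -> StandardSet:
    """Build a standard set from labeled feature vectors.

    The first ``per_subject`` vectors per subject (input order, i.e.
    chronological) are stored. When ``R_t`` is not given it is calibrated
    as the ``threshold_percentile`` of within-subject leave-one-out mean
    matched distances over the enrolled entries.
    """
    if not features:
        raise ValueError("cannot enroll an empty feature list")
    pairs: list[tuple[FeatureVector, str]] = []
    for item in features:
        if isinstance(item, FeatureVector):
            pairs.append((item, item.subject_id))
        else:
            fv, label = item
            pairs.append((fv, str(label)))

    by_subject: dict[str, list[FeatureVector]] = {}
    for fv, label in pairs:
        by_subject.setdefault(label, []).append(fv)

    rows, labels = [], []
    for label, fvs in by_subject.items():
        if len(fvs) < per_subject:
            warnings.warn(
                f"subject {label!r} has only {len(fvs)} feature vectors "
                f"(wanted {per_subject}); enrolling all of them",
                stacklevel=2,
            )
        for fv in fvs[:per_subject]:
            rows.append(fv.beta)
            labels.append(label)

    features_mat = np.vstack(rows)
    if R_t is None:
        R_t = calibrate_threshold(features_mat, labels, threshold_percentile)
    return StandardSet(features=features_mat, labels=labels, R_t=R_t, per_subject=per_subject)


def calibrate_threshold(
    features: np.ndarray, labels: list[str], percentile: float = 99.0
) -> float:
    """Leave-one-out within-subject calibration of R_t: for every enrolled
    vector, compute its mean matched distance against its own subject's
    remaining entries; R_t is the given percentile of those distances."""
    features = np.asarray(features, dtype=float)
    labels_arr = np.asarray(labels)
    dbars: list[float] = []
    for subject in np.unique(labels_arr):
        rows = np.flatnonzero(labels_arr == subject)
        if rows.size < 2:
            continue
        block = features[rows]  # (m, K)
        for i in range(rows.size):
            q = block[i]
            support = np.flatnonzero(q)
            if support.size == 0:
                continue
            others = np.delete(block, i, axis=0)
            dmin = np.min(np.abs(others[:, support] - q[support]), axis=0)
            dbars.append(float(dmin.mean()))
    if not dbars:
        logger.warning("no within-subject pairs for calibration; using R_t = 1.0")
        return 1.0
    return max(float(np.percentile(dbars, percentile)), 1e-9)


def _label_mean_distance(
    S: StandardSet, label: str, query: np.ndarray, support: np.ndarray
) -> float:
    block = S.features[S.subject_rows(label)]
    dmin = np.min(np.abs(block[:, support] - query[support]), axis=0)
    return float(dmin.mean())


def bundle_search(
    query: FeatureVector,
    S: StandardSet,
    weight_rule: str = "uniform",
    reject_mode: str = "mean",
    decision_rule: str = "distance",
) -> IdentificationResult:
    """Classify one feature vector against the standard set.

    Per nonzero coordinate i of the query, the distances
    ``|beta_i - beta^(z)_i|`` to every enrolled entry z are computed; the
    coordinate votes for the label of its nearest entry (earliest-enrolled
    entry wins coordinate ties). ``weight_rule="uniform"`` gives every
    vote weight 1; ``"inv_rank"`` ranks the coordinates by their nearest
    distance and weights the r-th most confident coordinate by 1/r.

    The predicted label is, with ``decision_rule="distance"`` (default),
    the subject minimizing the mean over the support of its per-coordinate
    minimum distance (the aggregated-distance argmin; ties lexicographic);
    with ``"votes"``, the label with the largest vote total (ties: smaller
    mean matched distance, then lexicographic). The query is rejected when
    its mean (or, with ``reject_mode="total"``, summed) matched distance
    to the winning label exceeds R_t.
    """
    beta = query.beta
    if beta.shape[0] != S.K:
        raise ValueError(f"query length {beta.shape[0]} != standard set K {S.K}")
    support = np.flatnonzero(beta)
    if support.size == 0:
        raise ValueError("query has no nonzero features to match")
    if weight_rule not in ("uniform", "inv_rank"):
        raise ValueError(f"unknown weight_rule {weight_rule!r}")
    if reject_mode not in ("mean", "total"):
        raise ValueError(f"unknown reject_mode {reject_mode!r}")
    if decision_rule not in ("distance", "votes"):
        raise ValueError(f"unknown decision_rule {decision_rule!r}")

    dist = np.abs(S.features[:, support] - beta[support])  # (M, |support|)
    nearest = np.argmin(dist, axis=0)  # first index wins ties
    min_dist = dist[nearest, np.arange(support.size)]

    if weight_rule == "uniform":
        weights = np.ones(support.size)
    else:
        order = np.argsort(min_dist, kind="stable")
        weights = np.empty(support.size)
        weights[order] = 1.0 / (np.arange(support.size) + 1.0)

    votes: dict[str, float] = {}
    for j, z in enumerate(nearest):
        label = S.labels[int(z)]
        votes[label] = votes.get(label, 0.0) + float(weights[j])

    if decision_rule == "distance":
        scored = [
            (_label_mean_distance(S, lb, beta, support), lb) for lb in S.subjects
        ]
        dbar, best = min(scored)  # ties lexicographic via tuple order
    else:
        max_vote = max(votes.values())
        tied = sorted(lb for lb, v in votes.items() if v == max_vote)
        if len(tied) == 1:
            best = tied[0]
            dbar = _label_mean_distance(S, best, beta, support)
        else:
            scored = [(_label_mean_distance(S, lb, beta, support), lb) for lb in tied]
            dbar, best = min(scored)

    d_stat = dbar * support.size if reject_mode == "total" else dbar
    predicted = REJECT if d_stat > S.R_t else best
    return IdentificationResult(
        predicted=predicted,
        votes=votes,
        mean_distance=dbar,
        threshold=S.R_t,
        best_label=best,
    )


@dataclass
class IdentificationMetrics:
    recognition_rate: float  # correct / non-rejected
    rejection_rate: float
    n_queries: int
    n_rejected: int
    confusion: pd.DataFrame


def evaluate_identification(
    test: list[tuple[FeatureVector, str]],
    S: StandardSet,
    weight_rule: str = "uniform",
    reject_mode: str = "mean",
    decision_rule: str = "distance",
) -> IdentificationMetrics:
    """Rank-1 recognition rate over non-rejected closed-set queries, plus
    rejection rate and per-subject confusion counts."""
    if not test:
        raise ValueError("test set must be nonempty")
    records = []
    for fv, true_label in test:
        res = bundle_search(
            fv, S, weight_rule=weight_rule, reject_mode=reject_mode,
            decision_rule=decision_rule,
        )
        records.append((true_label, res.predicted))
    df = pd.DataFrame(records, columns=["true", "predicted"])
    rejected = df["predicted"] == REJECT
    accepted = df[~rejected]
    rate = (
        float((accepted["true"] == accepted["predicted"]).mean())
        if len(accepted)
        else 0.0
    )
    confusion = pd.crosstab(df["true"], df["predicted"])
    return IdentificationMetrics(
        recognition_rate=rate,
        rejection_rate=float(rejected.mean()),
        n_queries=len(df),
        n_rejected=int(rejected.sum()),
        confusion=confusion,
    )
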