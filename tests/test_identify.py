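"""Enrollment and the co-dimensional bundle-search classifier."""

import numpy as np
import pytest

from ecgid import (
    REJECT,
    FeatureVector,
    StandardSet,
    bundle_search,
    enroll,
    evaluate_identification,
)


def fv(beta, sid=""):
    return FeatureVector(beta=np.asarray(beta, dtype=float), subject_id=sid)


def brute_force_bundle(query, entries, labels):
    """Independent enumeration of the coordinate-wise nearest-entry vote:
    for every nonzero coordinate i compute |beta_i - beta^(z)_i| over all
    entries z, vote for the nearest entry's label, and report the mean of
    the winner's per-coordinate minima."""
    query = np.asarray(query, dtype=float)
    support = [i for i in range(query.size) if query[i] != 0]
    votes: dict[str, int] = {}
    for i in support:
        dists = [abs(query[i] - e[i]) for e in entries]
        z = int(np.argmin(dists))
        votes[labels[z]] = votes.get(labels[z], 0) + 1
    winner = max(sorted(votes), key=lambda lb: votes[lb])
    rows = [e for e, lb in zip(entries, labels) if lb == winner]
    dbar = float(
        np.mean([min(abs(query[i] - e[i]) for e in rows) for i in support])
    )
    return winner, votes, dbar


@pytest.fixture
def two_subject_set():
    return StandardSet(
        features=np.array([[1.0, 0.0, 1.0, 0.0], [0.0, 1.0, 0.0, 1.0]]),
        labels=["A", "B"],
        R_t=0.5,
        per_subject=1,
    )


class TestEnroll:
    def _features(self, n_subjects, per, K=12, seed=0):
        rng = np.random.default_rng(seed)
        out = []
        for s in range(n_subjects):
            for _ in range(per):
                out.append(fv(np.abs(rng.standard_normal(K)), f"S{s:03d}"))
        return out

    def test_seventy_subjects_thirty_each(self):
        S = enroll(self._features(70, 30), per_subject=30, R_t=1.0)
        assert S.M == 2100
        assert len(S.subjects) == 70

    def test_underfilled_subject_warns_and_keeps_all(self):
        with pytest.warns(UserWarning, match="only 5"):
            S = enroll(self._features(1, 5), per_subject=30, R_t=1.0)
        assert S.M == 5

    def test_duplicate_labels_merge(self):
        feats = self._features(1, 4) + self._features(1, 4, seed=9)
        S = enroll(feats, per_subject=30, R_t=1.0)
        assert len(S.subjects) == 1 and S.M == 8

    def test_enrollment_truncates_chronologically(self):
        feats = self._features(1, 6)
        S = enroll(feats, per_subject=4, R_t=1.0)
        assert S.M == 4
        assert np.allclose(S.features[0], feats[0].beta)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            enroll([], R_t=1.0)

    def test_calibrated_threshold_is_positive(self):
        S = enroll(self._features(3, 10))
        assert S.R_t > 0


class TestBundleSearch:
    def test_enrolled_vector_matches_itself_exactly(self):
        rng = np.random.default_rng(3)
        feats = []
        for s in range(4):
            for _ in range(5):
                feats.append(fv(np.abs(rng.standard_normal(16)), f"S{s}"))
        S = enroll(feats, per_subject=5, R_t=1.0)
        res = bundle_search(feats[7], S)
        assert res.predicted == feats[7].subject_id
        assert res.mean_distance == 0.0

    @pytest.mark.parametrize("rule", ["distance", "votes"])
    def test_two_subject_worked_example(self, two_subject_set, rule):
        query = fv([0.9, 0.0, 0.9, 0.1])
        res = bundle_search(query, two_subject_set, decision_rule=rule)
        winner, votes, dbar = brute_force_bundle(
            query.beta,
            [two_subject_set.features[0], two_subject_set.features[1]],
            ["A", "B"],
        )
        assert winner == "A" and votes == {"A": 3}
        assert res.predicted == "A"
        assert res.votes == {"A": 3.0}
        assert np.isclose(res.mean_distance, 0.1)
        assert np.isclose(res.mean_distance, dbar)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(7)
        entries = [np.abs(rng.standard_normal(10)) * (rng.random(10) > 0.4) for _ in range(12)]
        labels = [f"S{i % 4}" for i in range(12)]
        S = StandardSet(np.vstack(entries), labels, R_t=100.0)
        for _ in range(20):
            q = np.abs(rng.standard_normal(10)) * (rng.random(10) > 0.5)
            if not q.any():
                continue
            res = bundle_search(fv(q), S, decision_rule="votes")
            winner, votes, dbar = brute_force_bundle(q, entries, labels)
            assert sum(res.votes.values()) == sum(votes.values())
            assert res.predicted == winner or (
                # vote tie resolved by mean distance, then lexicographic
                res.votes[res.predicted] == res.votes[winner]
            )
            if res.predicted == winner:
                assert np.isclose(res.mean_distance, dbar)

    def test_far_query_rejected(self, two_subject_set):
        S = StandardSet(
            two_subject_set.features, two_subject_set.labels, R_t=0.01
        )
        res = bundle_search(fv([5.0, 0.0, 5.0, 5.0]), S)
        assert res.predicted == REJECT
        assert res.best_label in ("A", "B")

    def test_monotone_rejection_in_threshold(self, two_subject_set):
        query = fv([0.9, 0.0, 0.9, 0.1])
        statuses = []
        for rt in (1.0, 0.15, 0.05, 0.01):
            S = StandardSet(two_subject_set.features, two_subject_set.labels, R_t=rt)
            statuses.append(bundle_search(query, S).predicted == REJECT)
        # once rejected at some threshold, rejected at every lower one
        assert statuses == sorted(statuses)

    def test_votes_conservation_uniform(self, two_subject_set):
        res = bundle_search(fv([0.9, 0.2, 0.9, 0.1]), two_subject_set)
        assert sum(res.votes.values()) == 4

    def test_entry_permutation_invariance(self):
        rng = np.random.default_rng(15)
        entries = np.abs(rng.standard_normal((9, 8)))
        labels = [f"S{i % 3}" for i in range(9)]
        S1 = StandardSet(entries, labels, R_t=10.0)
        perm = rng.permutation(9)
        S2 = StandardSet(entries[perm], [labels[i] for i in perm], R_t=10.0)
        q = fv(np.abs(rng.standard_normal(8)))
        r1, r2 = bundle_search(q, S1), bundle_search(q, S2)
        assert r1.predicted == r2.predicted
        assert np.isclose(r1.mean_distance, r2.mean_distance)

    def test_inv_rank_weights_sum_to_harmonic_number(self, two_subject_set):
        res = bundle_search(fv([0.9, 0.0, 0.9, 0.1]), two_subject_set, weight_rule="inv_rank")
        assert np.isclose(sum(res.votes.values()), 1 + 1 / 2 + 1 / 3)

    def test_all_zero_query_rejected_as_error(self, two_subject_set):
        with pytest.raises(ValueError):
            bundle_search(fv([0.0, 0.0, 0.0, 0.0]), two_subject_set)

    def test_dimension_mismatch(self, two_subject_set):
        with pytest.raises(ValueError):
            bundle_search(fv([1.0, 2.0]), two_subject_set)


class TestEvaluate:
    def test_enrolled_vectors_score_perfectly(self):
        rng = np.random.default_rng(21)
        feats = []
        for s in range(5):
            for _ in range(6):
                feats.append(fv(np.abs(rng.standard_normal(20)), f"S{s}"))
        S = enroll(feats, per_subject=6, R_t=1.0)
        test = [(f, f.subject_id) for f in feats]
        metrics = evaluate_identification(test, S)
        assert metrics.recognition_rate == 1.0
        assert metrics.rejection_rate == 0.0
        assert metrics.confusion.values.trace() == 30

    def test_empty_test_set_rejected(self):
        S = StandardSet(np.ones((1, 3)), ["A"], R_t=1.0)
        with pytest.raises(ValueError):
            evaluate_identification([], S)
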