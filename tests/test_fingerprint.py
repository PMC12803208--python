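"""Identification engine: similarity, matching, voting, permutations,
subsets, down-sampling, motion splits, task modes, static baseline."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from framefp.fingerprint import (
    DatabasePool,
    bootstrap_ci,
    chance_expectation,
    downsample_nodes,
    enumerate_database_subsets,
    identify_scan,
    match_volume,
    permutation_null,
    run_identification,
    similarity,
    split_by_motion,
    static_fingerprint,
    task_identification,
    truncate_to_common_length,
)
from framefp.cohort import CohortConfig, make_subnetwork_map
from framefp.experiments import pipeline_eigenseries
from framefp.phase import LeadingEigenSeries


def eig(subject, session, task, v1):
    v1 = np.asarray(v1, dtype=float)
    return LeadingEigenSeries(
        v1=v1,
        lambda1=np.full(v1.shape[0], float(v1.shape[1]) / 2),
        variance_fraction=np.full(v1.shape[0], 0.5),
        tr_seconds=2.2,
        subject_id=subject,
        session_id=session,
        task=task,
    )


def unit_rows(rng, n_rows, n):
    m = rng.standard_normal((n_rows, n))
    return m / np.linalg.norm(m, axis=1, keepdims=True)


class TestSimilarity:
    def test_identical_vectors(self, rng):
        v = rng.standard_normal(10)
        assert similarity(v, v) == pytest.approx(1.0)

    def test_negated_vector_also_one(self, rng):
        """An eigenvector and its negation encode the same connectivity."""
        v = rng.standard_normal(10)
        assert similarity(v, -v) == pytest.approx(1.0)

    def test_four_entry_toy_matches_hand_formula(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([2.0, 1.0, 5.0, 3.0])
        za, zb = a - a.mean(), b - b.mean()
        expected = abs((za @ zb) / np.sqrt((za @ za) * (zb @ zb)))
        assert similarity(a, b) == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=40, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetry_and_sign_invariance(self, seed):
        r = np.random.default_rng(seed)
        a, b = r.standard_normal((2, 8))
        s = similarity(a, b)
        assert similarity(b, a) == pytest.approx(s, abs=1e-12)
        assert similarity(-a, b) == pytest.approx(s, abs=1e-12)
        assert similarity(a, -b) == pytest.approx(s, abs=1e-12)
        assert 0.0 <= s <= 1.0

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            similarity(np.ones(5), np.arange(5.0))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            similarity(np.arange(4.0), np.arange(5.0))


def constructed_pair(rng, n, r_target):
    """Two unit vectors with a prescribed Pearson correlation, built by
    mixing a vector with an orthogonalised partner (Gram-Schmidt)."""
    a = rng.standard_normal(n)
    a -= a.mean()
    b = rng.standard_normal(n)
    b -= b.mean()
    b -= (b @ a) / (a @ a) * a  # orthogonal to a, both centered
    a /= np.linalg.norm(a)
    b /= np.linalg.norm(b)
    return a, r_target * a + np.sqrt(1 - r_target**2) * b


class TestMatchVolume:
    def test_exact_copy_wins_with_similarity_one(self, rng):
        target = unit_rows(rng, 1, 12)[0]
        pool = DatabasePool(
            [
                eig("sub-001", "ses-01", "rest", unit_rows(rng, 5, 12)),
                eig("sub-002", "ses-01", "rest", np.vstack([unit_rows(rng, 2, 12), target])),
            ]
        )
        m = match_volume(target, pool)
        assert m.best_subject == "sub-002"
        assert m.best_volume_index == 2
        assert m.similarity == pytest.approx(1.0)

    def test_known_correlations_order_the_match(self, rng):
        t, high = constructed_pair(rng, 20, 0.9)
        _, low = constructed_pair(rng, 20, 0.3)
        pool = DatabasePool(
            [
                eig("sub-001", "ses-01", "rest", high[None, :]),
                eig("sub-002", "ses-01", "rest", low[None, :]),
            ]
        )
        m = match_volume(t, pool)
        assert m.best_subject == "sub-001"
        assert m.similarity == pytest.approx(0.9, abs=1e-10)

    def test_exact_tie_resolved_lexicographically_with_warning(self, rng):
        v = unit_rows(rng, 1, 10)
        pool = DatabasePool(
            [
                eig("sub-002", "ses-01", "rest", v),
                eig("sub-001", "ses-01", "rest", v.copy()),
            ]
        )
        with pytest.warns(UserWarning, match="tie"):
            m = match_volume(v[0], pool)
        assert m.best_subject == "sub-001"


class TestIdentifyScan:
    def test_all_volumes_match_owner(self, rng):
        own = unit_rows(rng, 4, 15)
        target = eig("sub-001", "ses-02", "rest", own + 0.01 * unit_rows(rng, 4, 15))
        pool = DatabasePool(
            [
                eig("sub-001", "ses-01", "rest", own),
                eig("sub-002", "ses-01", "rest", unit_rows(rng, 4, 15)),
            ]
        )
        pred = identify_scan(target, pool)
        assert pred.correct and pred.volume_accuracy == 1.0

    def test_majority_vote_two_to_one(self, rng):
        va = unit_rows(rng, 2, 15)
        vb = unit_rows(rng, 1, 15)
        target = eig("sub-003", "ses-02", "rest", np.vstack([va, vb]))
        pool = DatabasePool(
            [
                eig("sub-A", "ses-01", "rest", va),
                eig("sub-B", "ses-01", "rest", vb),
            ]
        )
        pred = identify_scan(target, pool, true_label="sub-A")
        assert pred.predicted_label == "sub-A"
        assert pred.vote_counts == {"sub-A": 2, "sub-B": 1}
        assert sum(pred.vote_counts.values()) == pred.n_volumes

    def test_self_in_pool_yields_perfect_match(self, rng):
        """Self-consistency: a copy of the target in the database matches
        every volume at similarity 1."""
        v = unit_rows(rng, 6, 12)
        target = eig("sub-001", "ses-02", "rest", v)
        pool = DatabasePool(
            [
                eig("sub-001", "ses-01", "rest", v.copy()),  # duplicate content
                eig("sub-002", "ses-01", "rest", unit_rows(rng, 6, 12)),
            ]
        )
        pred = identify_scan(target, pool)
        assert pred.volume_accuracy == 1.0
        assert np.allclose(pred.similarities, 1.0, atol=1e-10)

    def test_target_inside_its_own_pool_rejected(self, rng):
        v = unit_rows(rng, 3, 10)
        target = eig("sub-001", "ses-01", "rest", v)
        pool = DatabasePool([target, eig("sub-002", "ses-01", "rest", v)])
        with pytest.raises(ValueError, match="own database"):
            identify_scan(target, pool)


class TestEnumerateSubsetsAndChance:
    @pytest.mark.parametrize("n, k, count", [(9, 5, 126), (5, 3, 10), (7, 7, 1)])
    def test_subset_counts(self, n, k, count):
        subsets = enumerate_database_subsets(n, k)
        assert len(subsets) == count
        assert len(set(subsets)) == count

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            enumerate_database_subsets(5, 0)
        with pytest.raises(ValueError):
            enumerate_database_subsets(5, 6)

    @pytest.mark.parametrize(
        "volumes, labels, expected",
        [(803, 10, 80.3), (259, 100, 2.59), (106, 3, 106 / 3)],
    )
    def test_chance_expectation(self, volumes, labels, expected):
        assert chance_expectation(volumes, labels) == pytest.approx(expected)


class TestRunIdentification:
    def test_strong_cohort_recovers_identity(self, strong_report):
        assert strong_report.volume_accuracy >= 0.95
        assert strong_report.scan_accuracy == 1.0

    def test_iteration_bookkeeping_single_database_scan(self, null_cohort):
        _, series = null_cohort
        report = run_identification(series, database_size=1)
        # 2 sessions: each target session has 1 remaining session -> 2 iterations
        assert report.config["n_target_database_iterations"] == 2

    def test_label_permutation_equivariance(self, null_cohort):
        """Renaming subjects consistently leaves accuracies unchanged."""
        import dataclasses

        _, series = null_cohort
        base = run_identification(series)
        renamed = [
            dataclasses.replace(e, subject_id=e.subject_id.replace("sub-", "person-"))
            for e in series
        ]
        swapped = run_identification(renamed)
        assert swapped.volume_accuracy == base.volume_accuracy
        assert swapped.scan_accuracy == base.scan_accuracy

    def test_invalid_database_size(self, null_cohort):
        _, series = null_cohort
        with pytest.raises(ValueError):
            run_identification(series, database_size=5)


class TestPermutationNull:
    def test_strong_signal_is_significant(self, strong_report):
        perm = permutation_null(strong_report, n_perm=100, seed=11)
        assert perm.volume.p_value <= 0.01
        assert perm.scan.p_value <= 0.01
        assert perm.volume.p_is_upper_bound or perm.volume.p_value > 0

    def test_null_distribution_centred_at_chance(self, null_cohort):
        cfg, series = null_cohort
        report = run_identification(series)
        perm = permutation_null(report, n_perm=100, seed=1)
        assert abs(perm.volume.null_values.mean() - 1 / cfg.n_subjects) < 0.03

    def test_observed_equals_null_when_signal_absent(self, null_cohort):
        """Under no signal, the observed accuracy is a typical null draw."""
        _, series = null_cohort
        report = run_identification(series)
        perm = permutation_null(report, n_perm=200, seed=2)
        assert perm.volume.p_value > 0.01

    def test_type_one_error_calibration(self):
        """Across independent null cohorts, rejections at alpha=0.05 stay
        inside the 99% binomial band (<= 4 of 20)."""
        rejections = 0
        for seed in range(20):
            cfg = CohortConfig(
                n_subjects=4, n_sessions=2, n_nodes=20, n_volumes=80,
                subject_weight=0.0, task_weight=0.0, subject_task_weight=0.0,
                group_weight=1.0, session_noise_weight=1.0, seed=seed,
            )
            series, _, _ = pipeline_eigenseries(cfg)
            report = run_identification(series)
            perm = permutation_null(report, n_perm=200, seed=seed)
            if perm.volume.p_value <= 0.05:  # upper-bound p (< 1/n_perm) rejects too
                rejections += 1
        assert rejections <= 4

    def test_p_value_in_unit_interval(self, strong_report):
        perm = permutation_null(strong_report, n_perm=50, seed=0)
        for r in (perm.volume, perm.scan):
            assert 0 < r.p_value <= 1


class TestTaskIdentification:
    @pytest.fixture(scope="class")
    def task_cohort(self):
        cfg = CohortConfig(
            n_subjects=4, n_sessions=3, n_nodes=40, n_volumes=120,
            tasks=("rest", "faces"), group_weight=0.5, subject_weight=0.5,
            task_weight=0.4, subject_task_weight=1.0,
            session_noise_weight=0.5, seed=7,
        )
        series, _, _ = pipeline_eigenseries(cfg)
        return truncate_to_common_length(series)

    def test_within_beats_between_with_subject_task_signal(self, task_cohort):
        within = task_identification(task_cohort, mode="within")
        between = task_identification(task_cohort, mode="between")
        assert within.volume_accuracy >= between.volume_accuracy

    def test_no_task_signal_is_chance(self):
        cfg = CohortConfig(
            n_subjects=3, n_sessions=2, n_nodes=30, n_volumes=100,
            tasks=("rest", "faces"), task_weight=0.0, subject_task_weight=0.0,
            subject_weight=0.5, seed=4,
        )
        series, _, _ = pipeline_eigenseries(cfg)
        report = task_identification(truncate_to_common_length(series), mode="within")
        assert abs(report.volume_accuracy - 0.5) < 0.2

    def test_between_excludes_target_owner(self, task_cohort):
        report = task_identification(task_cohort, mode="between")
        for p in report.predictions:
            owners = {k[0] for k in p.pool_scan_keys}
            assert p.target_key[0] not in owners

    def test_single_task_rejected(self, null_cohort):
        _, series = null_cohort
        with pytest.raises(ValueError, match="2 tasks"):
            task_identification(series, mode="within")

    def test_unequal_lengths_rejected(self, rng):
        series = [
            eig("sub-001", "ses-01", "rest", unit_rows(rng, 5, 10)),
            eig("sub-001", "ses-02", "faces", unit_rows(rng, 4, 10)),
        ]
        with pytest.raises(ValueError, match="unequal"):
            task_identification(series, mode="within")


class TestDownsampleNodes:
    def test_whole_subnetwork_returned(self):
        m = make_subnetwork_map(100, 17, seed=0)
        counts = np.zeros(17, dtype=int)
        counts[3] = m.counts()[3]
        subset = downsample_nodes(m, counts, seed=1)
        assert np.array_equal(subset, m.members(3))

    def test_exact_stratified_counts_100_of_1000(self):
        m = make_subnetwork_map(1000, 17, seed=2)
        ref = make_subnetwork_map(100, 17, seed=2).counts()
        subset = downsample_nodes(m, ref, seed=3)
        assert subset.size == 100
        picked = np.bincount(m.labels[subset], minlength=17)
        assert np.array_equal(picked, ref)

    def test_same_seed_same_subset(self):
        m = make_subnetwork_map(200, 17, seed=0)
        ref = make_subnetwork_map(50, 17, seed=0).counts()
        assert np.array_equal(
            downsample_nodes(m, ref, seed=9), downsample_nodes(m, ref, seed=9)
        )

    def test_infeasible_counts_rejected(self):
        m = make_subnetwork_map(20, 17, seed=0)
        with pytest.raises(ValueError):
            downsample_nodes(m, np.full(17, 5), seed=0)


class TestSplitByMotion:
    def test_no_flags_side_is_absent(self, rng):
        v = unit_rows(rng, 4, 10)
        target = eig("sub-001", "ses-02", "rest", v)
        pool = DatabasePool(
            [eig("sub-001", "ses-01", "rest", v.copy()),
             eig("sub-002", "ses-01", "rest", unit_rows(rng, 4, 10))]
        )
        pred = identify_scan(target, pool)
        from framefp.fingerprint import IdentificationReport

        report = IdentificationReport([pred], "identity")
        flagged, clean = split_by_motion(
            report, {target.key: np.zeros(4, dtype=bool)}
        )
        assert flagged is None
        assert clean == report.volume_accuracy

    def test_all_flagged_symmetric_case(self, rng):
        v = unit_rows(rng, 4, 10)
        target = eig("sub-001", "ses-02", "rest", v)
        pool = DatabasePool(
            [eig("sub-001", "ses-01", "rest", v.copy()),
             eig("sub-002", "ses-01", "rest", unit_rows(rng, 4, 10))]
        )
        pred = identify_scan(target, pool)
        from framefp.fingerprint import IdentificationReport

        report = IdentificationReport([pred], "identity")
        flagged, clean = split_by_motion(
            report, {target.key: np.ones(4, dtype=bool)}
        )
        assert clean is None
        assert flagged == report.volume_accuracy

    def test_length_mismatch_rejected(self, strong_report):
        bad = {p.target_key: np.zeros(3, dtype=bool) for p in strong_report.predictions}
        with pytest.raises(ValueError, match="length"):
            split_by_motion(strong_report, bad)


class TestStaticFingerprint:
    def test_duplicate_network_identified(self, rng):
        net = np.corrcoef(rng.standard_normal((30, 6)), rowvar=False)
        other = np.corrcoef(rng.standard_normal((30, 6)), rowvar=False)
        report = static_fingerprint(
            {
                ("sub-001", "ses-01", "rest"): net,
                ("sub-001", "ses-02", "rest"): net.copy(),
                ("sub-002", "ses-01", "rest"): other,
            }
        )
        by_key = {p.target_key: p for p in report.predictions}
        assert by_key[("sub-001", "ses-02", "rest")].correct

    def test_block_distinct_two_subject_toy_is_perfect(self, rng):
        """Subjects with disjoint block structure are always identified."""
        def block_net(which):
            net = np.eye(8) * 1.0
            idx = (slice(0, 4),) * 2 if which == 0 else (slice(4, 8),) * 2
            net[idx] = 0.9
            np.fill_diagonal(net, 1.0)
            return net + 0.01 * rng.standard_normal((8, 8))

        networks = {}
        for subject, which in (("sub-001", 0), ("sub-002", 1)):
            for session in ("ses-01", "ses-02"):
                networks[(subject, session, "rest")] = block_net(which)
        report = static_fingerprint(networks)
        assert report.scan_accuracy == 1.0

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="shape"):
            static_fingerprint(
                {
                    ("sub-001", "ses-01", "rest"): np.eye(5),
                    ("sub-002", "ses-02", "rest"): np.eye(6),
                }
            )


class TestBootstrapCi:
    def test_interval_brackets_point_estimate(self, strong_report):
        ci = bootstrap_ci(strong_report, n_boot=500, seed=1)
        lo, hi = ci["volume_accuracy"]
        assert 0 <= lo <= strong_report.volume_accuracy <= hi <= 1

    def test_deterministic_under_seed(self, strong_report):
        a = bootstrap_ci(strong_report, n_boot=200, seed=5)
        b = bootstrap_ci(strong_report, n_boot=200, seed=5)
        assert a == b
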