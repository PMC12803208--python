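"""Single-volume connectome fingerprinting: target/database matching,
scan-level voting, chance arithmetic, permutation nulls, subset sweeps,
stratified node down-sampling, motion splits, task identification, and the
static-network baseline.

The core procedure: every volume of a target scan is represented by the
leading eigenvector of its phase-coherence matrix; the database is the set of
such vectors from all labelled reference scans. Each target volume is
assigned the label of the most similar database volume, where similarity is
the absolute Pearson correlation of the two eigenvectors (absolute, because
an eigenvector and its negation generate the identical rank-1 connectivity
pattern). Accuracy is scored at the volume level (fraction of volumes whose
best match carries the correct label) and at the scan level (majority vote of
the volume predictions).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from .phase import LeadingEigenSeries
from .records import SubnetworkMap

__all__ = [
    "DatabasePool",
    "VolumeMatch",
    "ScanPrediction",
    "IdentificationReport",
    "PermutationResult",
    "PermutationTest",
    "similarity",
    "match_volume",
    "identify_scan",
    "run_identification",
    "enumerate_database_subsets",
    "chance_expectation",
    "permutation_null",
    "task_identification",
    "downsample_nodes",
    "split_by_motion",
    "static_fingerprint",
    "bootstrap_ci",
]

_BLOCK = 4096  # database volumes scored per block; the full target-by-database
# similarity matrix is never materialised.


def _standardize_rows(m: np.ndarray, strict: bool = True) -> np.ndarray:
    """Center and unit-normalise each row, so |row_a . row_b| = |Pearson r|.

    A constant row has no defined correlation. In strict mode that raises;
    in batch (non-strict) mode the row is zeroed with a warning, so it
    correlates at 0 with everything and can never be a best match. Constant
    eigenvectors arise only when every node's phase aligns exactly (e.g. a
    global signal spike), so this is a rare, degenerate frame.
    """
    m = np.asarray(m, dtype=float)
    centered = m - m.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1, keepdims=True)
    dead = np.flatnonzero(norms[:, 0] == 0)
    if dead.size:
        if strict:
            raise ValueError(
                f"constant vector at volume {dead[0]}: Pearson correlation undefined"
            )
        warnings.warn(
            f"{dead.size} constant eigenvector(s) (fully phase-aligned frames); "
            "treated as zero-similarity to everything",
            stacklevel=3,
        )
        centered[dead] = 0.0
        norms[dead] = 1.0
    return centered / norms


def similarity(v_a: np.ndarray, v_b: np.ndarray) -> float:
    """Absolute Pearson correlation between two eigenvectors, in [0, 1]."""
    v_a = np.asarray(v_a, dtype=float)
    v_b = np.asarray(v_b, dtype=float)
    if v_a.shape != v_b.shape or v_a.ndim != 1:
        raise ValueError("vectors must be 1-D and of equal length")
    if v_a.size < 3:
        raise ValueError("need at least 3 entries for a meaningful correlation")
    z = _standardize_rows(np.vstack([v_a, v_b]))
    return float(min(abs(z[0] @ z[1]), 1.0))


@dataclass
class DatabasePool:
    """Labelled collection of eigenvector series acting as the database.

    ``label_kind`` selects which label a match predicts: ``"identity"``
    (subject) or ``"task"``. Volumes are indexable globally; each keeps a
    pointer to its source scan so scan-level label permutation is possible.
    """

    entries: list[LeadingEigenSeries]
    label_kind: str = "identity"

    # filled by __post_init__
    scan_keys: list[tuple[str, str, str]] = field(default_factory=list, repr=False)
    scan_labels: list[str] = field(default_factory=list, repr=False)
    _z: np.ndarray | None = field(default=None, repr=False)
    _vol_scan: np.ndarray | None = field(default=None, repr=False)
    _vol_index: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("database pool must be non-empty")
        if self.label_kind not in ("identity", "task"):
            raise ValueError("label_kind must be 'identity' or 'task'")
        # deterministic ordering: lexicographic by (subject, session, task)
        self.entries = sorted(self.entries, key=lambda e: e.key)
        self.scan_keys = [e.key for e in self.entries]
        if len(set(self.scan_keys)) != len(self.scan_keys):
            raise ValueError("duplicate scan in database pool")
        self.scan_labels = [self.label_of(e) for e in self.entries]
        self._z = _standardize_rows(
            np.vstack([e.v1 for e in self.entries]), strict=False
        )
        counts = [e.n_volumes for e in self.entries]
        self._vol_scan = np.repeat(np.arange(len(self.entries)), counts)
        self._vol_index = np.concatenate([np.arange(c) for c in counts])

    def label_of(self, series: LeadingEigenSeries) -> str:
        return series.subject_id if self.label_kind == "identity" else series.task

    @property
    def n_volumes(self) -> int:
        return int(self._z.shape[0])

    @property
    def labels(self) -> list[str]:
        return sorted(set(self.scan_labels))

    def best_matches(self, target_v1: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Best database volume for each target volume.

        Returns ``(flat_index, similarity)`` arrays, streaming over the
        database in blocks. Exact similarity ties are resolved toward the
        lowest (subject, session, task, volume) — the pool is sorted, so the
        smallest flat index wins — with a warning.
        """
        zt = _standardize_rows(np.atleast_2d(target_v1), strict=False)
        n_t = zt.shape[0]
        best = np.zeros(n_t, dtype=int)
        best_sim = np.full(n_t, -1.0)
        tied = np.zeros(n_t, dtype=bool)
        for start in range(0, self.n_volumes, _BLOCK):
            block = self._z[start : start + _BLOCK]
            sims = np.abs(zt @ block.T)
            idx = np.argmax(sims, axis=1)
            top = sims[np.arange(n_t), idx]
            tied |= top == best_sim
            better = top > best_sim
            best[better] = start + idx[better]
            best_sim[better] = top[better]
            # within-block exact ties: argmax already picks the first
            tied |= (sims == top[:, None]).sum(axis=1) > 1
        if tied.any():
            warnings.warn(
                f"{int(tied.sum())} exact similarity tie(s); "
                "resolved toward the lowest (subject, session, volume)",
                stacklevel=2,
            )
        return best, np.minimum(best_sim, 1.0)


@dataclass
class VolumeMatch:
    """Outcome of matching one target volume against the database."""

    target_volume_index: int
    best_subject: str
    best_session: str
    best_task: str
    best_volume_index: int
    similarity: float
    predicted_label: str
    correct: bool


@dataclass
class ScanPrediction:
    """Per-scan identification outcome (volume matches plus majority vote)."""

    target_key: tuple[str, str, str]
    true_label: str
    vote_counts: dict[str, int]
    predicted_label: str
    n_correct_volumes: int
    n_volumes: int
    pool_scan_keys: list[tuple[str, str, str]]
    pool_scan_labels: list[str]
    best_scan_idx: np.ndarray
    similarities: np.ndarray
    volume_correct: np.ndarray

    @property
    def volume_accuracy(self) -> float:
        return self.n_correct_volumes / self.n_volumes

    @property
    def correct(self) -> bool:
        return self.predicted_label == self.true_label


@dataclass
class IdentificationReport:
    """Aggregate of scan predictions for one identification run.

    ``volume_accuracy`` pools correct volumes over all targets;
    ``scan_accuracy`` is the fraction of target scans whose majority vote
    picked the true label.
    """

    predictions: list[ScanPrediction]
    label_kind: str
    config: dict = field(default_factory=dict)

    @property
    def n_targets(self) -> int:
        return len(self.predictions)

    @property
    def volume_accuracy(self) -> float:
        total = sum(p.n_volumes for p in self.predictions)
        correct = sum(p.n_correct_volumes for p in self.predictions)
        return correct / total

    @property
    def scan_accuracy(self) -> float:
        return float(np.mean([p.correct for p in self.predictions]))

    def mean_correct_volumes(self) -> float:
        """Average number of correct volumes per target scan."""
        return float(np.mean([p.n_correct_volumes for p in self.predictions]))

    def summary(self) -> dict:
        return {
            "n_targets": self.n_targets,
            "volume_accuracy": self.volume_accuracy,
            "scan_accuracy": self.scan_accuracy,
            "mean_correct_volumes": self.mean_correct_volumes(),
            "label_kind": self.label_kind,
            **self.config,
        }


def match_volume(target_v1: np.ndarray, pool: DatabasePool) -> VolumeMatch:
    """Most similar database volume for one target eigenvector."""
    idx, sim = pool.best_matches(target_v1)
    scan_i = int(pool._vol_scan[idx[0]])
    key = pool.scan_keys[scan_i]
    label = pool.scan_labels[scan_i]
    return VolumeMatch(
        target_volume_index=0,
        best_subject=key[0],
        best_session=key[1],
        best_task=key[2],
        best_volume_index=int(pool._vol_index[idx[0]]),
        similarity=float(sim[0]),
        predicted_label=label,
        correct=False,  # caller decides against its own true label
    )


def _majority_vote(
    labels: np.ndarray, sims: np.ndarray, candidates: list[str]
) -> tuple[str, dict[str, int]]:
    """Majority vote with ties broken by total similarity of winning votes."""
    counts = {c: int(np.sum(labels == c)) for c in candidates}
    top = max(counts.values())
    winners = [c for c, n in counts.items() if n == top]
    if len(winners) == 1:
        return winners[0], counts
    sums = {c: float(sims[labels == c].sum()) for c in winners}
    best = max(sums.values())
    final = sorted(c for c, s in sums.items() if s == best)[0]
    return final, counts


def identify_scan(
    target: LeadingEigenSeries, pool: DatabasePool, true_label: str | None = None
) -> ScanPrediction:
    """Match every target volume against the pool and take the majority vote."""
    if true_label is None:
        true_label = pool.label_of(target)
    for key in pool.scan_keys:
        if key == target.key:
            raise ValueError(f"target scan {key} present in its own database pool")
    idx, sims = pool.best_matches(target.v1)
    scan_idx = pool._vol_scan[idx]
    labels = np.asarray(pool.scan_labels, dtype=object)[scan_idx]
    correct = labels == true_label
    predicted, counts = _majority_vote(labels, sims, pool.labels)
    return ScanPrediction(
        target_key=target.key,
        true_label=true_label,
        vote_counts=counts,
        predicted_label=predicted,
        n_correct_volumes=int(correct.sum()),
        n_volumes=target.n_volumes,
        pool_scan_keys=pool.scan_keys,
        pool_scan_labels=list(pool.scan_labels),
        best_scan_idx=scan_idx.astype(int),
        similarities=sims,
        volume_correct=correct.astype(bool),
    )


def enumerate_database_subsets(n_candidates: int, k: int) -> list[tuple[int, ...]]:
    """All C(n, k) index subsets in deterministic lexicographic order."""
    if not (1 <= k <= n_candidates):
        raise ValueError(f"k must be in [1, {n_candidates}], got {k}")
    return list(itertools.combinations(range(n_candidates), k))


def chance_expectation(n_volumes: int, n_labels: int) -> float:
    """Correct volumes expected by chance: volumes per scan / candidate labels."""
    if n_labels < 1:
        raise ValueError("need at least one candidate label")
    return n_volumes / n_labels


def run_identification(
    eigenseries: list[LeadingEigenSeries],
    database_size: int | None = None,
    label_kind: str = "identity",
    max_subsets_per_target: int | None = None,
) -> IdentificationReport:
    """Full identity-identification sweep over target sessions.

    Every scan serves as the target once per database subset: for each target
    session, the database is built from ``database_size`` of the remaining
    sessions (all subjects), and every such session subset is enumerated.
    With ``database_size=None`` all remaining sessions form the database
    (one subset). ``max_subsets_per_target`` caps the enumeration for large
    sweeps (the first subsets in lexicographic order are kept, so the cap is
    deterministic).
    """
    if label_kind != "identity":
        raise ValueError("use task_identification() for task labels")
    sessions = sorted({e.session_id for e in eigenseries})
    by_session: dict[str, list[LeadingEigenSeries]] = {s: [] for s in sessions}
    for e in eigenseries:
        by_session[e.session_id].append(e)
    if len(sessions) < 2:
        raise ValueError("identity identification needs >= 2 sessions")
    n_db_sessions = len(sessions) - 1
    k = n_db_sessions if database_size is None else database_size
    if not (1 <= k <= n_db_sessions):
        raise ValueError(
            f"database_size must be in [1, {n_db_sessions}], got {k}"
        )

    predictions: list[ScanPrediction] = []
    n_iterations = 0
    for target_session in sessions:
        others = [s for s in sessions if s != target_session]
        subsets = enumerate_database_subsets(len(others), k)
        if max_subsets_per_target is not None:
            subsets = subsets[:max_subsets_per_target]
        for subset in subsets:
            chosen = [others[i] for i in subset]
            pool_entries = [e for s in chosen for e in by_session[s]]
            pool = DatabasePool(pool_entries, label_kind="identity")
            n_iterations += 1
            for target in sorted(by_session[target_session], key=lambda e: e.key):
                predictions.append(identify_scan(target, pool))
    return IdentificationReport(
        predictions=predictions,
        label_kind="identity",
        config={
            "database_size": k,
            "n_sessions": len(sessions),
            "n_target_database_iterations": n_iterations,
        },
    )


@dataclass
class PermutationResult:
    """Null distribution of one accuracy statistic under label permutation."""

    observed: float
    null_values: np.ndarray
    p_value: float
    p_is_upper_bound: bool = False

    @property
    def p_text(self) -> str:
        return (
            f"< {self.p_value:.6g}" if self.p_is_upper_bound else f"{self.p_value:.6g}"
        )


@dataclass
class PermutationTest:
    """Permutation nulls for both accuracy levels of one report."""

    volume: PermutationResult
    scan: PermutationResult
    n_perm: int
    seed: int


def permutation_null(
    report: IdentificationReport, n_perm: int, seed: int = 0
) -> PermutationTest:
    """Scan-label permutation null for volume- and scan-level accuracy.

    Database scan labels are shuffled as a multiset (label counts preserved);
    every volume keeps its scan's permuted label. Because the best-matching
    database volume does not depend on labels, the cached per-volume match
    indices are simply re-labelled for each permutation — identical to
    re-running the identification with permuted databases. The p-value is the
    fraction of permutations with performance equal or superior to the
    observed one; a zero count is reported as an upper bound of 1/n_perm
    rather than zero.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    obs_vol = report.volume_accuracy
    obs_scan = report.scan_accuracy
    total_volumes = sum(p.n_volumes for p in report.predictions)

    # group predictions by their pool so one permutation relabels each pool once
    pools: dict[tuple, list[ScanPrediction]] = {}
    for p in report.predictions:
        pools.setdefault(tuple(p.pool_scan_keys), []).append(p)

    null_vol = np.empty(n_perm)
    null_scan = np.empty(n_perm)
    for i in range(n_perm):
        correct_volumes = 0
        correct_scans = 0
        n_targets = 0
        for key, preds in pools.items():
            base_labels = np.asarray(preds[0].pool_scan_labels, dtype=object)
            perm_labels = base_labels[rng.permutation(len(base_labels))]
            candidates = sorted(set(perm_labels.tolist()))
            for p in preds:
                labels = perm_labels[p.best_scan_idx]
                correct_volumes += int(np.sum(labels == p.true_label))
                predicted, _ = _majority_vote(labels, p.similarities, candidates)
                correct_scans += int(predicted == p.true_label)
                n_targets += 1
        null_vol[i] = correct_volumes / total_volumes
        null_scan[i] = correct_scans / n_targets

    def _result(observed: float, null: np.ndarray) -> PermutationResult:
        count = int(np.sum(null >= observed))
        if count == 0:
            return PermutationResult(observed, null, 1.0 / n_perm, True)
        return PermutationResult(observed, null, count / n_perm, False)

    return PermutationTest(
        volume=_result(obs_vol, null_vol),
        scan=_result(obs_scan, null_scan),
        n_perm=n_perm,
        seed=seed,
    )


def task_identification(
    eigenseries: list[LeadingEigenSeries],
    mode: str = "within",
) -> IdentificationReport:
    """Task identification with subject-scoped database pooling.

    ``within``: the database holds only the *target subject's* other
    sessions (all tasks) — tests whether a subject's own task repertoire
    identifies the task. ``between``: the database holds only *other
    subjects'* scans (all tasks, sessions other than the target session);
    every scan of the target's owner is excluded — tests whether task
    signatures generalise across people.

    All series should already be truncated to a common volume count (rest
    runs cut to the task length) so every task contributes equally; a
    ValueError names any length mismatch.
    """
    if mode not in ("within", "between"):
        raise ValueError("mode must be 'within' or 'between'")
    tasks = sorted({e.task for e in eigenseries})
    if len(tasks) < 2:
        raise ValueError("task identification needs >= 2 tasks")
    lengths = {e.n_volumes for e in eigenseries}
    if len(lengths) > 1:
        raise ValueError(
            f"scans have unequal volume counts {sorted(lengths)}; "
            "truncate to a common length first"
        )
    predictions: list[ScanPrediction] = []
    for target in sorted(eigenseries, key=lambda e: e.key):
        if mode == "within":
            pool_entries = [
                e
                for e in eigenseries
                if e.subject_id == target.subject_id
                and e.session_id != target.session_id
            ]
        else:
            pool_entries = [
                e
                for e in eigenseries
                if e.subject_id != target.subject_id
                and e.session_id != target.session_id
            ]
        if not pool_entries:
            raise ValueError(f"empty database pool for target {target.key}")
        pool = DatabasePool(pool_entries, label_kind="task")
        predictions.append(identify_scan(target, pool, true_label=target.task))
    return IdentificationReport(
        predictions=predictions,
        label_kind="task",
        config={"mode": mode, "tasks": tasks},
    )


def truncate_to_common_length(
    eigenseries: list[LeadingEigenSeries],
) -> list[LeadingEigenSeries]:
    """Truncate every series to the shortest series' volume count."""
    t = min(e.n_volumes for e in eigenseries)
    return [e.truncate(t) for e in eigenseries]


def downsample_nodes(
    subnetworks: SubnetworkMap,
    reference_counts: np.ndarray | dict[int, int],
    seed: int = 0,
) -> np.ndarray:
    """Stratified node subset matching per-subnetwork reference counts.

    Emulates sampling a coarse atlas's node budget out of a fine atlas while
    holding the number of nodes per subnetwork fixed. Returns sorted node
    indices; deterministic under ``seed``.
    """
    if isinstance(reference_counts, dict):
        counts = np.zeros(subnetworks.n_subnetworks, dtype=int)
        for k, v in reference_counts.items():
            counts[k] = v
    else:
        counts = np.asarray(reference_counts, dtype=int)
    if counts.shape != (subnetworks.n_subnetworks,):
        raise ValueError("one reference count per subnetwork required")
    rng = np.random.default_rng(seed)
    chosen: list[np.ndarray] = []
    for k in range(subnetworks.n_subnetworks):
        members = subnetworks.members(k)
        want = int(counts[k])
        if want > members.size:
            raise ValueError(
                f"subnetwork {k} has {members.size} nodes, cannot sample {want}"
            )
        if want:
            chosen.append(rng.choice(members, size=want, replace=False))
    return np.sort(np.concatenate(chosen)) if chosen else np.empty(0, dtype=int)


def split_by_motion(
    report: IdentificationReport,
    flags_by_target: dict[tuple[str, str, str], np.ndarray],
) -> tuple[float | None, float | None]:
    """Volume-level accuracy over motion-flagged vs unflagged volumes.

    ``flags_by_target`` maps each target scan key to its per-volume flag
    vector, already aligned with the (trimmed) eigen-series indexing. Returns
    ``(accuracy_flagged, accuracy_unflagged)``; a side with no volumes is
    reported as None.
    """
    flagged_correct = flagged_total = 0
    clean_correct = clean_total = 0
    for p in report.predictions:
        flags = np.asarray(flags_by_target[p.target_key], dtype=bool)
        if flags.shape != (p.n_volumes,):
            raise ValueError(
                f"flags for {p.target_key} have length {flags.shape[0]}, "
                f"expected {p.n_volumes}"
            )
        flagged_correct += int(p.volume_correct[flags].sum())
        flagged_total += int(flags.sum())
        clean_correct += int(p.volume_correct[~flags].sum())
        clean_total += int((~flags).sum())
    acc_flagged = flagged_correct / flagged_total if flagged_total else None
    acc_clean = clean_correct / clean_total if clean_total else None
    return acc_flagged, acc_clean


def _upper_triangle(matrix: np.ndarray) -> np.ndarray:
    n = matrix.shape[0]
    iu = np.triu_indices(n, k=1)
    return matrix[iu]


def static_fingerprint(
    networks: dict[tuple[str, str, str], np.ndarray],
    label_kind: str = "identity",
) -> IdentificationReport:
    """Whole-scan fingerprinting from static (Pearson) networks.

    The classical protocol: each target session's network is matched against
    every other session's networks by the (signed) Pearson correlation of
    their vectorised upper triangles; the owner of the most correlated
    database network is the prediction. Scan-level accuracy only — there is
    one network per scan, no volumes to vote with.
    """
    keys = sorted(networks)
    if len(keys) < 2:
        raise ValueError("need at least two networks")
    n = next(iter(networks.values())).shape[0]
    for key, mat in networks.items():
        if mat.shape != (n, n):
            raise ValueError(f"network {key} has shape {mat.shape}, expected ({n},{n})")
    vectors = _standardize_rows(
        np.vstack([_upper_triangle(networks[k]) for k in keys]), strict=False
    )
    labels = [k[0] if label_kind == "identity" else k[2] for k in keys]
    sessions = [k[1] for k in keys]

    predictions: list[ScanPrediction] = []
    for i, key in enumerate(keys):
        mask = np.array([sessions[j] != sessions[i] for j in range(len(keys))])
        if not mask.any():
            raise ValueError("no database networks outside the target session")
        sims = vectors[mask] @ vectors[i]  # signed r, per the static protocol
        pool_idx = np.flatnonzero(mask)
        best = pool_idx[int(np.argmax(sims))]
        predicted = labels[best]
        true_label = labels[i]
        predictions.append(
            ScanPrediction(
                target_key=key,
                true_label=true_label,
                vote_counts={predicted: 1},
                predicted_label=predicted,
                n_correct_volumes=int(predicted == true_label),
                n_volumes=1,
                pool_scan_keys=[keys[j] for j in pool_idx],
                pool_scan_labels=[labels[j] for j in pool_idx],
                best_scan_idx=np.array([int(np.flatnonzero(pool_idx == best)[0])]),
                similarities=np.array([float(np.max(sims))]),
                volume_correct=np.array([predicted == true_label]),
            )
        )
    return IdentificationReport(
        predictions=predictions,
        label_kind=label_kind,
        config={"method": "static"},
    )


def bootstrap_ci(
    report: IdentificationReport,
    n_boot: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict[str, tuple[float, float]]:
    """Percentile bootstrap CIs over target scans for both accuracy levels."""
    rng = np.random.default_rng(seed)
    vol_acc = np.array([p.volume_accuracy for p in report.predictions])
    scan_ok = np.array([p.correct for p in report.predictions], dtype=float)
    n = len(vol_acc)
    idx = rng.integers(0, n, size=(n_boot, n))
    vol_means = vol_acc[idx].mean(axis=1)
    scan_means = scan_ok[idx].mean(axis=1)
    lo, hi = 100 * alpha / 2, 100 * (1 - alpha / 2)
    return {
        "volume_accuracy": tuple(np.percentile(vol_means, [lo, hi])),
        "scan_accuracy": tuple(np.percentile(scan_means, [lo, hi])),
    }
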