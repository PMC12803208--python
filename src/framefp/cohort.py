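"""Synthetic multi-subject, multi-session, multi-task BOLD cohort generator.

The generator produces node time series whose correlation structure mixes
four low-rank covariance components, each built once per cohort from a
seeded standard-normal loading matrix F (N x latent_rank) as F F^T:

* a group component G shared by every scan,
* a subject component S_s stable across that subject's sessions and tasks,
* a task component K_k shared by all subjects performing task k,
* a subject-by-task component I_{s,k} unique to that pairing.

For a scan by subject s in session e on task k the node signal is

    x(t) = sqrt(w_g) G u_g(t) + sqrt(w_s) S_s u_s(t)
         + sqrt(w_k) K_k u_k(t) + sqrt(w_sk) I_sk u_sk(t) + sigma eps(t)

with all latent series u and the white noise eps drawn fresh per session, so
E[x x^T] = w_g GG^T + w_s S_sS_s^T + w_k K_kK_k^T + w_sk I_skI_sk^T +
sigma^2 I. The series are then band-limited to the resting-state BOLD band
with the same zero-phase filter the preprocessing module uses (instantaneous
phases are only meaningful for narrowband signals), and a constant baseline
is added so percent-signal-change and tSNR are well defined.

Identity information therefore lives in the subject (and subject-by-task)
covariance: sessions of one subject share correlation structure that other
subjects lack, which is exactly the premise single-frame fingerprinting
tests. Setting ``subject_weight = task_weight = subject_task_weight = 0``
makes all scans exchangeable and identification can only succeed at chance.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace

import numpy as np

from .prep import MIN_FILTER_LENGTH, bandpass_array
from .records import ScanRecord, SubnetworkMap

__all__ = [
    "CohortConfig",
    "generate_cohort",
    "generate_motion",
    "make_subnetwork_map",
    "preset_config",
    "PRESETS",
]


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of a synthetic cohort.

    ``n_volumes`` is the raw, pre-trimming volume count; per-task overrides
    go in ``task_volumes`` (e.g. short task runs alongside a long rest run).
    The mixing weights are variances of the respective covariance components
    relative to unit-variance latent factors; ``session_noise_weight`` is the
    white-noise standard deviation. Defaults give a moderately identifiable
    cohort: the subject component is comparable to the shared group component
    and the noise floor, so identification is well above chance without being
    saturated.
    """

    n_subjects: int = 10
    n_sessions: int = 4
    n_nodes: int = 50
    n_volumes: int = 200
    tr_seconds: float = 2.2
    tasks: tuple[str, ...] = ("rest",)
    group_weight: float = 1.0
    subject_weight: float = 0.6
    task_weight: float = 0.3
    subject_task_weight: float = 0.15
    session_noise_weight: float = 1.0
    latent_rank: int = 10
    band_low_hz: float = 0.009
    band_high_hz: float = 0.08
    motion_spike_rate: float = 0.0
    seed: int = 0
    task_volumes: tuple[tuple[str, int], ...] = ()
    baseline: float = 1000.0
    voxel_budget: int | None = None
    steady_state_drop: int = 5

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("need at least 2 nodes")
        if self.n_subjects < 1 or self.n_sessions < 1:
            raise ValueError("need at least one subject and one session")
        if not self.tasks:
            raise ValueError("need at least one task")
        weights = (
            self.group_weight,
            self.subject_weight,
            self.task_weight,
            self.subject_task_weight,
            self.session_noise_weight,
        )
        if not all(np.isfinite(w) and w >= 0 for w in weights):
            raise ValueError("mixing weights must be finite and non-negative")
        if self.latent_rank < 1:
            raise ValueError("latent_rank must be >= 1")
        nyquist = 0.5 / self.tr_seconds
        if not (0 < self.band_low_hz < self.band_high_hz < nyquist):
            raise ValueError("band edges must satisfy 0 < low < high < Nyquist")
        if not (0 <= self.motion_spike_rate <= 1):
            raise ValueError("motion_spike_rate must be a probability")
        shortest = min(
            [self.n_volumes] + [t for _, t in self.task_volumes], default=self.n_volumes
        )
        if shortest < MIN_FILTER_LENGTH:
            raise ValueError(
                f"scans of {shortest} volumes are too short for a stable "
                f"band-pass (minimum {MIN_FILTER_LENGTH})"
            )

    def volumes_for(self, task: str) -> int:
        return dict(self.task_volumes).get(task, self.n_volumes)


def _scan_rng(config: CohortConfig, *labels: str) -> np.random.Generator:
    """Deterministic per-scan generator derived from the cohort seed."""
    tag = zlib.crc32("/".join(labels).encode())
    return np.random.default_rng(np.random.SeedSequence([config.seed, tag]))


def _noise_sd(config: CohortConfig) -> float:
    """White-noise sd, optionally scaled by a fixed voxel budget.

    With ``voxel_budget`` set, each node is treated as the average of
    ``voxel_budget // n_nodes`` voxels carrying independent unit-variance
    measurement noise: finer parcellations average fewer voxels per node and
    so are noisier, which is what drives the tSNR difference between coarse
    and fine atlases.
    """
    if config.voxel_budget is None:
        return config.session_noise_weight
    per_node = max(config.voxel_budget // config.n_nodes, 1)
    return config.session_noise_weight / np.sqrt(per_node)


def generate_cohort(config: CohortConfig) -> list[ScanRecord]:
    """Generate all ``n_subjects x n_sessions x len(tasks)`` scans.

    Identical configs (including seed) produce bit-identical cohorts: all
    loading matrices are drawn in a fixed order from the master seed and each
    scan's session-level randomness comes from a generator keyed on
    (seed, subject, session, task).
    """
    master = np.random.default_rng(config.seed)
    n, r = config.n_nodes, config.latent_rank

    group = master.standard_normal((n, r))
    subject_loadings = [
        master.standard_normal((n, r)) for _ in range(config.n_subjects)
    ]
    task_loadings = {task: master.standard_normal((n, r)) for task in config.tasks}
    st_loadings = {
        (s, task): master.standard_normal((n, r))
        for s in range(config.n_subjects)
        for task in config.tasks
    }

    sigma = _noise_sd(config)
    scans: list[ScanRecord] = []
    for s in range(config.n_subjects):
        subj = f"sub-{s + 1:03d}"
        for e in range(config.n_sessions):
            sess = f"ses-{e + 1:02d}"
            for task in config.tasks:
                t = config.volumes_for(task)
                rng = _scan_rng(config, subj, sess, task)
                x = np.zeros((t, n))
                for weight, loading, stream_tag in (
                    (config.group_weight, group, "g"),
                    (config.subject_weight, subject_loadings[s], "s"),
                    (config.task_weight, task_loadings[task], "k"),
                    (config.subject_task_weight, st_loadings[(s, task)], "sk"),
                ):
                    u = rng.standard_normal((t, r))
                    if weight > 0:
                        x += np.sqrt(weight) * (u @ loading.T)
                if sigma > 0:
                    x += sigma * rng.standard_normal((t, n))
                x = bandpass_array(
                    x, config.tr_seconds, config.band_low_hz, config.band_high_hz
                )
                data = config.baseline + x
                fd = np.concatenate([[0.0], rng.uniform(0.02, 0.3, size=t - 1)])
                scan = ScanRecord(
                    subject_id=subj,
                    session_id=sess,
                    task=task,
                    data=data,
                    tr_seconds=config.tr_seconds,
                    motion_fd=fd,
                    global_signal=data.mean(axis=1),
                )
                if config.motion_spike_rate > 0:
                    scan = generate_motion(config, scan)
                scans.append(scan)
    return scans


def generate_motion(config: CohortConfig, scan: ScanRecord) -> ScanRecord:
    """Inject motion-spike volumes at rate ``motion_spike_rate``.

    At each spike volume (never the first): framewise displacement is drawn
    above the 0.5 mm scrubbing threshold; a common signal step of ~8% of the
    baseline hits every node (so the global-signal change exceeds the 5%
    flagging criterion); and per-node noise several times the scan's own
    temporal sd corrupts the data, emulating the signal disruption that makes
    high-motion frames less identifiable. Non-spike volumes keep FD below
    0.5 mm. Deterministic given the config seed and the scan's labels.
    """
    rng = _scan_rng(config, *scan.key, "motion")
    t = scan.n_volumes
    spikes = np.flatnonzero(rng.random(t) < config.motion_spike_rate)
    spikes = spikes[spikes > 0]

    fd = np.concatenate([[0.0], rng.uniform(0.02, 0.3, size=t - 1)])
    data = scan.data.copy()
    if spikes.size:
        fd[spikes] = 0.5 + rng.exponential(0.3, size=spikes.size)
        signal_sd = float(np.mean(data.std(axis=0)))
        steps = (
            config.baseline
            * rng.uniform(0.06, 0.12, size=spikes.size)
            * rng.choice([-1.0, 1.0], size=spikes.size)
        )
        data[spikes] += steps[:, None]
        data[spikes] += 5.0 * signal_sd * rng.standard_normal(
            (spikes.size, data.shape[1])
        )
    return scan.replace(data=data, motion_fd=fd, global_signal=data.mean(axis=1))


def make_subnetwork_map(
    n_nodes: int, n_subnetworks: int = 17, seed: int = 0
) -> SubnetworkMap:
    """Random balanced assignment of nodes to subnetworks.

    Subnetwork sizes differ by at most one (the first ``n_nodes mod
    n_subnetworks`` subnetworks get the extra node); which nodes land where
    is a seeded permutation.
    """
    if n_nodes < n_subnetworks:
        raise ValueError(
            f"cannot place {n_nodes} nodes into {n_subnetworks} non-empty subnetworks"
        )
    base = n_nodes // n_subnetworks
    remainder = n_nodes % n_subnetworks
    sizes = [base + (1 if k < remainder else 0) for k in range(n_subnetworks)]
    labels = np.repeat(np.arange(n_subnetworks), sizes)
    rng = np.random.default_rng(seed)
    labels = labels[rng.permutation(n_nodes)]
    return SubnetworkMap(labels=labels, n_subnetworks=n_subnetworks)


# Study-shaped presets: dimensions mirror the three cohorts the method was
# demonstrated on, so chance-level arithmetic (volumes per scan / candidate
# labels) comes out the same. Signal weights stay at the defaults — they are
# free parameters of the synthetic model, not estimates of real effect sizes.
PRESETS: dict[str, CohortConfig] = {
    # 10 subjects x 10 sessions; 818-volume rest runs and 121-volume task
    # runs at TR 2.2 s; first 5 volumes dropped for steady state.
    "msc": CohortConfig(
        n_subjects=10,
        n_sessions=10,
        n_nodes=100,
        n_volumes=818,
        tr_seconds=2.2,
        tasks=("rest", "faces", "words"),
        task_volumes=(("faces", 121), ("words", 121)),
        steady_state_drop=5,
    ),
    # 100 subjects x 6 longitudinal sessions; 274-volume rest at TR 2.2 s.
    "ncanda": CohortConfig(
        n_subjects=100,
        n_sessions=6,
        n_nodes=100,
        n_volumes=274,
        tr_seconds=2.2,
        tasks=("rest",),
        steady_state_drop=5,
    ),
    # 173 subjects x 2 sessions; 217-volume rest at TR 2.0 s; first 10
    # volumes dropped.
    "bnet": CohortConfig(
        n_subjects=173,
        n_sessions=2,
        n_nodes=100,
        n_volumes=217,
        tr_seconds=2.0,
        tasks=("rest",),
        steady_state_drop=10,
    ),
}


def preset_config(name: str, **overrides) -> CohortConfig:
    """A study-shaped preset, optionally with overridden fields.

    Overrides are how scaled-down variants are made (fewer subjects or nodes
    for quick runs) while keeping the preset's timing and session structure.
    """
    try:
        base = PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
    return replace(base, **overrides) if overrides else base
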