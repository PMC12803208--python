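"""Experiment orchestration: the simulate -> prep -> phase -> identify grid,
node down-sampling repeats, and tSNR comparisons across parcellation sizes.

Each grid cell runs the full pipeline on a freshly generated synthetic cohort
and records both accuracy levels, the matching chance expectation, optional
permutation p-values, and a motion split when spikes were simulated. Cell
failures are isolated: a failed cell is recorded with its error message and
the run continues.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np

from .cohort import CohortConfig, generate_cohort, make_subnetwork_map, preset_config
from .fingerprint import (
    IdentificationReport,
    bootstrap_ci,
    chance_expectation,
    downsample_nodes,
    permutation_null,
    run_identification,
    split_by_motion,
    task_identification,
    truncate_to_common_length,
)
from .phase import (
    EDGE_TRIM_DEFAULT,
    LeadingEigenSeries,
    eigenseries_from_scan,
    trim_edge_artifact,
)
from .prep import PreprocConfig, mean_tsnr, preprocess_scan

__all__ = [
    "ExperimentConfig",
    "run_experiment",
    "run_downsample_experiment",
    "report_tsnr_comparison",
    "pipeline_eigenseries",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """Grid of identification runs over one synthetic preset.

    ``preset`` names a study-shaped cohort; the override fields scale it to
    the problem size of the run (the full preset dimensions are only needed
    for chance arithmetic, which uses the preset itself). ``node_counts`` and
    ``database_sizes`` span the grid. ``task_modes`` adds within/between task
    identification cells when the preset has >= 2 tasks.
    """

    preset: str = "msc"
    node_counts: tuple[int, ...] = (50,)
    database_sizes: tuple[int, ...] = (None,)  # None = all remaining sessions
    n_perm: int = 0
    task_modes: tuple[str, ...] = ()
    downsample_iterations: int = 100
    seed: int = 0
    n_subjects: int | None = None
    n_sessions: int | None = None
    n_volumes: int | None = None
    motion_spike_rate: float | None = None
    subject_weight: float | None = None
    edge_trim: int = EDGE_TRIM_DEFAULT
    max_subsets_per_target: int | None = None

    def cohort_config(self, n_nodes: int) -> CohortConfig:
        overrides: dict = {"n_nodes": n_nodes, "seed": self.seed}
        for name in ("n_subjects", "n_sessions", "n_volumes", "motion_spike_rate",
                     "subject_weight"):
            value = getattr(self, name)
            if value is not None:
                overrides[name] = value
        return preset_config(self.preset, **overrides)


def pipeline_eigenseries(
    cohort_config: CohortConfig,
    preproc: PreprocConfig | None = None,
    edge_trim: int = EDGE_TRIM_DEFAULT,
    node_subset: np.ndarray | None = None,
):
    """Generate, preprocess, and reduce a cohort to eigen series.

    Returns ``(eigenseries, trimmed_flags_by_key, mean_tsnr_per_scan)``.
    ``node_subset`` restricts the analysis to the given node indices after
    generation (used by the down-sampling experiment).
    """
    if preproc is None:
        preproc = PreprocConfig(steady_state_drop=cohort_config.steady_state_drop)
    scans = generate_cohort(cohort_config)
    series: list[LeadingEigenSeries] = []
    flags_by_key: dict[tuple[str, str, str], np.ndarray] = {}
    tsnr_by_key: dict[tuple[str, str, str], float] = {}
    for scan in scans:
        if node_subset is not None:
            scan = scan.replace(
                data=scan.data[:, node_subset],
                global_signal=None,  # recompute over the subset
            )
        result = preprocess_scan(scan, preproc)
        tsnr_by_key[scan.key] = mean_tsnr(result.tsnr)
        eig = eigenseries_from_scan(result.scan, trim=edge_trim)
        series.append(eig)
        if result.motion_flags is not None:
            flags_by_key[scan.key] = trim_edge_artifact(
                result.motion_flags, edge_trim
            )
    return series, flags_by_key, tsnr_by_key


def _cell_payload(
    report: IdentificationReport,
    n_labels: int,
    n_perm: int,
    seed: int,
    flags_by_key: dict | None = None,
) -> dict:
    n_volumes = report.predictions[0].n_volumes
    payload = {
        **report.summary(),
        "chance_correct_volumes": chance_expectation(n_volumes, n_labels),
        "n_volumes_per_scan": n_volumes,
        "bootstrap_95ci": bootstrap_ci(report, seed=seed),
    }
    if n_perm > 0:
        perm = permutation_null(report, n_perm=n_perm, seed=seed)
        payload["permutation"] = {
            "n_perm": n_perm,
            "volume_p": perm.volume.p_text,
            "scan_p": perm.scan.p_text,
        }
    if flags_by_key:
        flagged, clean = split_by_motion(report, flags_by_key)
        payload["motion_split"] = {
            "accuracy_flagged": flagged,
            "accuracy_unflagged": clean,
        }
    return payload


@dataclass
class ExperimentReport:
    """All grid cells of one experiment run, JSON-serialisable via asdict."""

    cells: dict[str, dict] = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {"cells": self.cells, "failures": self.failures, "config": self.config}

    def summary_table(self) -> str:
        """Human-readable fixed-width summary of every cell."""
        lines = [f"{'cell':<40} {'vol_acc':>8} {'scan_acc':>9} {'chance':>8}"]
        for name, cell in sorted(self.cells.items()):
            lines.append(
                f"{name:<40} {cell['volume_accuracy']:>8.3f} "
                f"{cell['scan_accuracy']:>9.3f} "
                f"{cell['chance_correct_volumes']:>8.2f}"
            )
        for name, err in sorted(self.failures.items()):
            lines.append(f"{name:<40} FAILED: {err}")
        return "\n".join(lines)


def run_experiment(config: ExperimentConfig) -> ExperimentReport:
    """Run every (node count x database size) cell, plus task-mode cells."""
    report = ExperimentReport(config=dataclasses.asdict(config))
    for n_nodes in config.node_counts:
        try:
            cohort_cfg = config.cohort_config(n_nodes)
            series, flags, tsnr = pipeline_eigenseries(
                cohort_cfg, edge_trim=config.edge_trim
            )
            rest = [s for s in series if s.task == cohort_cfg.tasks[0]]
        except Exception as exc:  # noqa: BLE001 - isolate cell failures
            for k in config.database_sizes:
                report.failures[f"nodes={n_nodes}/dbsize={k}"] = str(exc)
            continue
        for k in config.database_sizes:
            name = f"nodes={n_nodes}/dbsize={'all' if k is None else k}"
            try:
                ident = run_identification(
                    rest,
                    database_size=k,
                    max_subsets_per_target=config.max_subsets_per_target,
                )
                cell = _cell_payload(
                    ident,
                    n_labels=cohort_cfg.n_subjects,
                    n_perm=config.n_perm,
                    seed=config.seed,
                    flags_by_key={
                        key: flg for key, flg in flags.items()
                        if key in {p.target_key for p in ident.predictions}
                    } if flags else None,
                )
                cell["mean_tsnr"] = float(np.mean(list(tsnr.values())))
                report.cells[name] = cell
            except Exception as exc:  # noqa: BLE001
                report.failures[name] = str(exc)
        for mode in config.task_modes:
            name = f"nodes={n_nodes}/task-{mode}"
            try:
                common = truncate_to_common_length(series)
                ident = task_identification(common, mode=mode)
                report.cells[name] = _cell_payload(
                    ident,
                    n_labels=len(cohort_cfg.tasks),
                    n_perm=config.n_perm,
                    seed=config.seed,
                )
            except Exception as exc:  # noqa: BLE001
                report.failures[name] = str(exc)
    return report


def run_downsample_experiment(
    config: ExperimentConfig,
    n_nodes_full: int,
    reference_counts: np.ndarray,
    n_subnetworks: int = 17,
    iterations: int | None = None,
    database_size: int | None = None,
) -> dict:
    """Stratified node down-sampling repeated ``iterations`` times.

    A single large-parcellation cohort is generated once; each iteration
    samples a node subset that matches the per-subnetwork ``reference_counts``
    of a coarse parcellation, reruns the full analysis on that subset, and
    records accuracy. Reports mean and sd over iterations.
    """
    iterations = config.downsample_iterations if iterations is None else iterations
    cohort_cfg = config.cohort_config(n_nodes_full)
    subnet = make_subnetwork_map(n_nodes_full, n_subnetworks, seed=config.seed)
    scans = generate_cohort(cohort_cfg)
    preproc = PreprocConfig(steady_state_drop=cohort_cfg.steady_state_drop)

    vol_accs, scan_accs = [], []
    for it in range(iterations):
        subset = downsample_nodes(subnet, reference_counts, seed=config.seed + it)
        series = []
        for scan in scans:
            sub = scan.replace(data=scan.data[:, subset], global_signal=None)
            result = preprocess_scan(sub, preproc)
            if sub.task == cohort_cfg.tasks[0]:
                series.append(eigenseries_from_scan(result.scan, config.edge_trim))
        ident = run_identification(
            series,
            database_size=database_size,
            max_subsets_per_target=config.max_subsets_per_target,
        )
        vol_accs.append(ident.volume_accuracy)
        scan_accs.append(ident.scan_accuracy)
    return {
        "iterations": iterations,
        "n_nodes_full": n_nodes_full,
        "n_nodes_sampled": int(np.asarray(reference_counts).sum()),
        "volume_accuracy_mean": float(np.mean(vol_accs)),
        "volume_accuracy_sd": float(np.std(vol_accs, ddof=1)) if iterations > 1 else 0.0,
        "scan_accuracy_mean": float(np.mean(scan_accs)),
        "scan_accuracy_sd": float(np.std(scan_accs, ddof=1)) if iterations > 1 else 0.0,
    }


def report_tsnr_comparison(
    config_small_n: CohortConfig, config_large_n: CohortConfig
) -> dict:
    """Mean temporal SNR under two parcellation granularities.

    Both cohorts should share a ``voxel_budget`` so that the finer
    parcellation averages fewer voxels per node; the comparison then isolates
    the node-size effect on tSNR. Scans are paired by (subject, session,
    task) for the paired difference.
    """
    summaries = {}
    per_scan: dict[str, dict] = {}
    for tag, cfg in (("small_n", config_small_n), ("large_n", config_large_n)):
        preproc = PreprocConfig(steady_state_drop=cfg.steady_state_drop)
        values = {}
        for scan in generate_cohort(cfg):
            result = preprocess_scan(scan, preproc)
            values[scan.key] = mean_tsnr(result.tsnr)
        per_scan[tag] = values
        arr = np.array(list(values.values()))
        summaries[tag] = {
            "n_nodes": cfg.n_nodes,
            "mean_tsnr": float(arr.mean()),
            "sd_tsnr": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        }
    common = sorted(set(per_scan["small_n"]) & set(per_scan["large_n"]))
    diffs = np.array(
        [per_scan["small_n"][k] - per_scan["large_n"][k] for k in common]
    )
    summaries["paired_difference_small_minus_large"] = {
        "mean": float(diffs.mean()) if diffs.size else 0.0,
        "sd": float(diffs.std(ddof=1)) if diffs.size > 1 else 0.0,
        "n_pairs": len(common),
    }
    return summaries
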