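"""Core data containers shared across the pipeline.

All time-resolved arrays in this package are stored time-first: a scan's
``data`` has shape ``(n_volumes, n_nodes)``, matching the on-disk TSV layout
(one row per volume, one column per node).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ScanRecord", "SubnetworkMap", "scan_key"]


@dataclass
class ScanRecord:
    """One functional scan: node time series plus identifying labels.

    Parameters
    ----------
    subject_id, session_id, task
        Non-empty labels identifying the scan. ``(subject_id, session_id,
        task)`` is unique within a cohort.
    data
        ``(n_volumes, n_nodes)`` array of BOLD-like node time series.
    tr_seconds
        Repetition time (sampling interval) in seconds.
    motion_fd
        Optional per-volume framewise displacement in mm; first entry 0
        (no previous frame to displace from).
    global_signal
        Optional per-volume whole-brain mean signal, used for motion
        flagging. Defaults to the row mean of ``data`` when absent.
    """

    subject_id: str
    session_id: str
    task: str
    data: np.ndarray
    tr_seconds: float
    motion_fd: np.ndarray | None = None
    global_signal: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("subject_id", "session_id", "task"):
            if not getattr(self, name):
                raise ValueError(f"{name} must be a non-empty label")
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (n_volumes, n_nodes)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite entries")
        if not (self.tr_seconds > 0):
            raise ValueError("tr_seconds must be positive")
        for name in ("motion_fd", "global_signal"):
            trace = getattr(self, name)
            if trace is not None:
                trace = np.asarray(trace, dtype=float)
                if trace.shape != (self.n_volumes,):
                    raise ValueError(
                        f"{name} must have one entry per volume "
                        f"({trace.shape[0]} != {self.n_volumes})"
                    )
                setattr(self, name, trace)

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1]

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.subject_id, self.session_id, self.task)

    def effective_global_signal(self) -> np.ndarray:
        """Global signal trace, falling back to the per-volume node mean."""
        if self.global_signal is not None:
            return self.global_signal
        return self.data.mean(axis=1)

    def replace(self, **changes) -> "ScanRecord":
        """Return a copy with the given fields replaced (validates anew)."""
        return dataclasses.replace(self, **changes)


def scan_key(scan: ScanRecord | tuple[str, str, str]) -> tuple[str, str, str]:
    if isinstance(scan, ScanRecord):
        return scan.key
    return tuple(scan)  # type: ignore[return-value]


@dataclass(frozen=True)
class SubnetworkMap:
    """Assignment of every node to exactly one subnetwork.

    ``labels[i]`` is the integer subnetwork id of node ``i`` (ids are
    ``0 .. n_subnetworks-1``). Emulates coarse functional systems such as the
    17 canonical resting-state subnetworks used to stratify node sampling.
    """

    labels: np.ndarray = field()
    n_subnetworks: int = 17

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "labels", labels)
        if labels.ndim != 1:
            raise ValueError("labels must be 1-D")
        if labels.min(initial=0) < 0 or labels.max(initial=0) >= self.n_subnetworks:
            raise ValueError("label out of range")
        if len(labels) >= self.n_subnetworks:
            present = np.unique(labels)
            if len(present) != self.n_subnetworks:
                raise ValueError("every subnetwork must be non-empty")

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def members(self, subnetwork: int) -> np.ndarray:
        return np.flatnonzero(self.labels == subnetwork)

    def counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_subnetworks)
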