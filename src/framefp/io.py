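"""Plain-text serialization: per-scan TSVs, motion traces, eigen series, and
a JSON cohort manifest tying them together.

Layout of a cohort directory::

    manifest.json                       scan list + config provenance
    sub-001_ses-01_rest.tsv             volumes x nodes, header node_0001...
    sub-001_ses-01_rest_motion.tsv      columns: volume, fd_mm, global_signal
    eig/sub-001_ses-01_rest.tsv         volumes x nodes eigenvectors
    eig/sub-001_ses-01_rest_eigvals.tsv columns: volume, lambda1, variance_fraction
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .phase import LeadingEigenSeries
from .records import ScanRecord

__all__ = [
    "write_cohort",
    "read_cohort",
    "write_eigenseries",
    "read_eigenseries",
    "write_json",
]


def _stem(key: tuple[str, str, str]) -> str:
    return "_".join(key)


def _node_columns(n: int) -> list[str]:
    return [f"node_{i + 1:04d}" for i in range(n)]


def write_cohort(
    scans: list[ScanRecord], out_dir: str | Path, extra_manifest: dict | None = None
) -> Path:
    """Write one TSV (+ motion TSV) per scan and a JSON manifest; returns the
    manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for scan in scans:
        stem = _stem(scan.key)
        data_path = out / f"{stem}.tsv"
        pd.DataFrame(scan.data, columns=_node_columns(scan.n_nodes)).to_csv(
            data_path, sep="\t", index=False, float_format="%.6f"
        )
        entry = {
            "scan": data_path.name,
            "subject": scan.subject_id,
            "session": scan.session_id,
            "task": scan.task,
            "tr_seconds": scan.tr_seconds,
            "n_volumes": scan.n_volumes,
            "n_nodes": scan.n_nodes,
        }
        if scan.motion_fd is not None:
            motion_path = out / f"{stem}_motion.tsv"
            pd.DataFrame(
                {
                    "volume": np.arange(scan.n_volumes),
                    "fd_mm": scan.motion_fd,
                    "global_signal": scan.effective_global_signal(),
                }
            ).to_csv(motion_path, sep="\t", index=False, float_format="%.6f")
            entry["motion"] = motion_path.name
        entries.append(entry)
    manifest = {"scans": entries}
    if extra_manifest:
        manifest.update(extra_manifest)
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest_path


def read_cohort(directory: str | Path) -> list[ScanRecord]:
    """Read every scan listed in a cohort directory's manifest."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    scans = []
    for entry in manifest["scans"]:
        data = pd.read_csv(directory / entry["scan"], sep="\t").to_numpy()
        motion_fd = global_signal = None
        if "motion" in entry:
            motion = pd.read_csv(directory / entry["motion"], sep="\t")
            motion_fd = motion["fd_mm"].to_numpy()
            global_signal = motion["global_signal"].to_numpy()
        scans.append(
            ScanRecord(
                subject_id=entry["subject"],
                session_id=entry["session"],
                task=entry["task"],
                data=data,
                tr_seconds=entry["tr_seconds"],
                motion_fd=motion_fd,
                global_signal=global_signal,
            )
        )
    return scans


def write_eigenseries(
    series: list[LeadingEigenSeries], out_dir: str | Path, extra_manifest: dict | None = None
) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for s in series:
        stem = _stem(s.key)
        vec_path = out / f"{stem}.tsv"
        pd.DataFrame(s.v1, columns=_node_columns(s.n_nodes)).to_csv(
            vec_path, sep="\t", index=False, float_format="%.8f"
        )
        val_path = out / f"{stem}_eigvals.tsv"
        pd.DataFrame(
            {
                "volume": np.arange(s.n_volumes),
                "lambda1": s.lambda1,
                "variance_fraction": s.variance_fraction,
            }
        ).to_csv(val_path, sep="\t", index=False, float_format="%.8f")
        entries.append(
            {
                "vectors": vec_path.name,
                "eigvals": val_path.name,
                "subject": s.subject_id,
                "session": s.session_id,
                "task": s.task,
                "tr_seconds": s.tr_seconds,
                "n_volumes": s.n_volumes,
                "n_nodes": s.n_nodes,
            }
        )
    manifest = {"eigenseries": entries}
    if extra_manifest:
        manifest.update(extra_manifest)
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest_path


def read_eigenseries(directory: str | Path) -> list[LeadingEigenSeries]:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    series = []
    for entry in manifest["eigenseries"]:
        v1 = pd.read_csv(directory / entry["vectors"], sep="\t").to_numpy()
        vals = pd.read_csv(directory / entry["eigvals"], sep="\t")
        series.append(
            LeadingEigenSeries(
                v1=v1,
                lambda1=vals["lambda1"].to_numpy(),
                variance_fraction=vals["variance_fraction"].to_numpy(),
                tr_seconds=entry["tr_seconds"],
                subject_id=entry["subject"],
                session_id=entry["session"],
                task=entry["task"],
            )
        )
    return series


def write_json(payload: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        raise TypeError(f"not JSON-serializable: {type(obj)}")

    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=_default))
    return path
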