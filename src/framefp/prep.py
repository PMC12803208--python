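"""Node-level preprocessing: steady-state trimming, band-pass filtering,
confound regression, motion-volume flagging, and temporal SNR.

The pipeline order is fixed: drop initial volumes, band-pass filter, regress
confounds. Motion flags are computed from the raw (unfiltered) displacement
and global-signal traces after the steady-state drop; tSNR is computed on the
raw series, before filtering and regression, so that its scale is comparable
across configurations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .records import ScanRecord

__all__ = [
    "PreprocConfig",
    "PreprocResult",
    "drop_initial_volumes",
    "bandpass",
    "bandpass_array",
    "regress_confounds",
    "flag_motion_volumes",
    "compute_tsnr",
    "mean_tsnr",
    "fd_from_motion_params",
    "preprocess_scan",
    "MIN_FILTER_LENGTH",
]

logger = logging.getLogger(__name__)

#: Minimum series length for the zero-phase band-pass (forward-backward
#: filtering of a 2nd-order band-pass needs > 3 * (n_coeffs) padding samples).
MIN_FILTER_LENGTH = 16


@dataclass(frozen=True)
class PreprocConfig:
    """Preprocessing parameters.

    ``steady_state_drop`` is the number of initial volumes discarded while the
    longitudinal magnetisation reaches equilibrium (5 volumes for the 2.2 s-TR
    presets, 10 for the 2.0 s-TR preset). The pass band of 0.009-0.08 Hz is
    the standard resting-state BOLD band. ``regress_global_mean`` toggles the
    (debated) global-signal regressor. A volume is flagged as high-motion only
    when framewise displacement of at least ``motion_fd_threshold_mm`` mm
    co-occurs with a global BOLD change of at least
    ``bold_change_threshold_fraction`` of the scan's mean global signal.
    """

    steady_state_drop: int = 5
    band_low_hz: float = 0.009
    band_high_hz: float = 0.08
    regress_global_mean: bool = True
    regress_motion: bool = True
    motion_fd_threshold_mm: float = 0.5
    bold_change_threshold_fraction: float = 0.05
    filter_order: int = 2

    def __post_init__(self) -> None:
        if self.steady_state_drop < 0:
            raise ValueError("steady_state_drop must be >= 0")
        if not (0 < self.band_low_hz < self.band_high_hz):
            raise ValueError("band edges must satisfy 0 < low < high")
        if self.motion_fd_threshold_mm <= 0 or self.bold_change_threshold_fraction <= 0:
            raise ValueError("motion thresholds must be positive")


def drop_initial_volumes(scan: ScanRecord, k: int) -> ScanRecord:
    """Remove the first ``k`` volumes from the data and all per-volume traces."""
    if k < 0:
        raise ValueError("k must be >= 0")
    if k >= scan.n_volumes:
        raise ValueError(
            f"cannot drop {k} volumes from a {scan.n_volumes}-volume scan"
        )
    if k == 0:
        return scan
    return scan.replace(
        data=scan.data[k:],
        motion_fd=None if scan.motion_fd is None else scan.motion_fd[k:],
        global_signal=None if scan.global_signal is None else scan.global_signal[k:],
    )


def bandpass_array(
    data: np.ndarray,
    tr_seconds: float,
    band_low_hz: float = 0.009,
    band_high_hz: float = 0.08,
    order: int = 2,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along axis 0 (time).

    Each column is demeaned, then filtered forward and backward (filtfilt) so
    that no phase distortion is introduced — essential because instantaneous
    phases are extracted downstream. The DC component is removed exactly by
    the demeaning; the band-pass keeps it out.
    """
    data = np.asarray(data, dtype=float)
    if not np.all(np.isfinite(data)):
        raise ValueError("cannot filter non-finite data")
    n = data.shape[0]
    if n < MIN_FILTER_LENGTH:
        raise ValueError(
            f"series too short to filter stably: {n} < {MIN_FILTER_LENGTH} volumes"
        )
    nyquist = 0.5 / tr_seconds
    if not (band_low_hz < band_high_hz < nyquist):
        raise ValueError(
            f"band [{band_low_hz}, {band_high_hz}] Hz not below Nyquist {nyquist:.4f} Hz"
        )
    sos = sps.butter(
        order,
        [band_low_hz, band_high_hz],
        btype="bandpass",
        fs=1.0 / tr_seconds,
        output="sos",
    )
    centered = data - data.mean(axis=0, keepdims=True)
    filtered = sps.sosfiltfilt(sos, centered, axis=0)
    # finite-length filtering leaves a small residual mean; remove it so the
    # output is exactly zero-mean per node
    return filtered - filtered.mean(axis=0, keepdims=True)


def bandpass(scan: ScanRecord, config: PreprocConfig) -> ScanRecord:
    """Band-pass filter every node series of a scan (motion traces untouched)."""
    filtered = bandpass_array(
        scan.data,
        scan.tr_seconds,
        config.band_low_hz,
        config.band_high_hz,
        config.filter_order,
    )
    return scan.replace(data=filtered)


def regress_confounds(scan: ScanRecord, regressors: np.ndarray | None) -> ScanRecord:
    """Replace each node series by its least-squares residual.

    An intercept column is always included, so with no regressors the result
    is simply the demeaned series. Collinear (rank-deficient) columns are
    dropped with a warning rather than raising; the residual is then computed
    against the reduced design. Residuals are orthogonal to every retained
    regressor column.
    """
    t = scan.n_volumes
    if regressors is None:
        regressors = np.empty((t, 0))
    regressors = np.atleast_2d(np.asarray(regressors, dtype=float))
    if regressors.shape[0] != t:
        if regressors.shape[1] == t:  # accept (k, T) for convenience
            regressors = regressors.T
        else:
            raise ValueError(
                f"regressors must have {t} rows, got shape {regressors.shape}"
            )
    if not np.all(np.isfinite(regressors)):
        raise ValueError("regressors contain non-finite entries")

    design = np.column_stack([np.ones(t), regressors])
    # Drop collinear columns via rank-revealing QR on the column-scaled design.
    q, r, piv = _qr_column_select(design)
    if len(piv) < design.shape[1]:
        dropped = sorted(set(range(design.shape[1])) - set(piv))
        warnings.warn(
            f"dropping {len(dropped)} collinear confound column(s): {dropped}",
            stacklevel=2,
        )
        design = design[:, piv]
    beta, *_ = np.linalg.lstsq(design, scan.data, rcond=None)
    residual = scan.data - design @ beta
    return scan.replace(data=residual)


def _qr_column_select(design: np.ndarray, rtol: float = 1e-10) -> tuple:
    """Pivoted-QR selection of a maximal independent column subset."""
    from scipy.linalg import qr

    q, r, piv = qr(design, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    if diag.size == 0 or diag[0] == 0:
        return q, r, [0]
    keep = piv[diag > rtol * diag[0]]
    return q, r, sorted(keep.tolist())


def flag_motion_volumes(scan: ScanRecord, config: PreprocConfig) -> np.ndarray:
    """Binary vector marking volumes with motion coupled to a BOLD change.

    Volume ``t`` (t >= 1) is flagged iff framewise displacement is at least
    the FD threshold AND the absolute change in global signal from the
    previous volume is at least the configured fraction of the scan's mean
    global signal. The first volume is never flagged (no previous frame).
    Both conditions are required: motion without a signal change, or a signal
    change without motion, leaves the volume unflagged.
    """
    if scan.motion_fd is None:
        raise ValueError("scan has no framewise-displacement trace")
    g = scan.effective_global_signal()
    reference = np.abs(g.mean())
    if reference == 0:
        raise ValueError("mean global signal is zero; BOLD-change fraction undefined")
    change = np.zeros_like(g)
    change[1:] = np.abs(np.diff(g)) / reference
    flags = (scan.motion_fd >= config.motion_fd_threshold_mm) & (
        change >= config.bold_change_threshold_fraction
    )
    flags[0] = False
    return flags


def compute_tsnr(scan: ScanRecord) -> np.ndarray:
    """Per-node temporal SNR: temporal mean over temporal standard deviation.

    Computed on the series as given (the pipeline calls this on the raw,
    unfiltered data). Zero-variance nodes are undefined and returned as NaN;
    use :func:`mean_tsnr` to average over the defined nodes only.
    """
    if scan.n_volumes < 2:
        raise ValueError("tSNR needs at least 2 volumes")
    mean = scan.data.mean(axis=0)
    sd = scan.data.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tsnr = np.where(sd > 0, mean / sd, np.nan)
    return tsnr


def mean_tsnr(tsnr: np.ndarray) -> float:
    """Average tSNR over nodes where it is defined."""
    defined = tsnr[np.isfinite(tsnr)]
    if defined.size == 0:
        raise ValueError("tSNR undefined for every node")
    return float(defined.mean())


def fd_from_motion_params(params: np.ndarray, head_radius_mm: float = 50.0) -> np.ndarray:
    """Framewise displacement from 6 rigid-body parameters.

    ``params`` is (T, 6): three translations in mm and three rotations in
    radians. Rotations are converted to arc length on a sphere of
    ``head_radius_mm``. FD(t) is the sum of absolute backward differences;
    FD(0) = 0.
    """
    params = np.asarray(params, dtype=float)
    if params.ndim != 2 or params.shape[1] != 6:
        raise ValueError("motion parameters must be (T, 6)")
    scaled = params.copy()
    scaled[:, 3:] *= head_radius_mm
    fd = np.zeros(len(params))
    fd[1:] = np.abs(np.diff(scaled, axis=0)).sum(axis=1)
    return fd


@dataclass
class PreprocResult:
    """Output of the full node-level preprocessing of one scan."""

    scan: ScanRecord
    motion_flags: np.ndarray | None
    tsnr: np.ndarray
    config: PreprocConfig


def preprocess_scan(scan: ScanRecord, config: PreprocConfig) -> PreprocResult:
    """Run the fixed pipeline: drop -> (tSNR, flags on raw) -> filter -> regress.

    Confound regressors assembled per config: the global-signal trace, the FD
    trace, and one indicator column per motion-flagged volume (the spike
    regressor), each only when available/enabled.
    """
    n_before = scan.n_volumes
    scan = drop_initial_volumes(scan, config.steady_state_drop)
    logger.info(
        "steady-state drop: %d -> %d volumes (%s)", n_before, scan.n_volumes, scan.key
    )
    tsnr = compute_tsnr(scan)
    flags = None
    if scan.motion_fd is not None:
        flags = flag_motion_volumes(scan, config)

    columns: list[np.ndarray] = []
    if config.regress_global_mean:
        columns.append(scan.effective_global_signal())
    if config.regress_motion and scan.motion_fd is not None:
        columns.append(scan.motion_fd)
    if flags is not None and flags.any():
        # one spike indicator per flagged volume, standard scrubbing regressors
        spikes = np.zeros((scan.n_volumes, int(flags.sum())))
        spikes[np.flatnonzero(flags), np.arange(int(flags.sum()))] = 1.0
        columns.append(spikes)

    scan = bandpass(scan, config)
    regressors = np.column_stack(columns) if columns else None
    scan = regress_confounds(scan, regressors)
    return PreprocResult(scan=scan, motion_flags=flags, tsnr=tsnr, config=config)
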