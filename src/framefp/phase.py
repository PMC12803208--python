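"""Per-volume phase-coherence connectivity and leading-eigenvector frames.

Each volume of a scan yields an N x N coherence matrix
``dFC(i, j, t) = cos(theta(i, t) - theta(j, t))`` where theta is the
instantaneous phase from the Hilbert transform of the band-limited node
series. Writing ``c = cos(theta_t)`` and ``s = sin(theta_t)``, the matrix is
``c c^T + s s^T``: symmetric, positive semidefinite, unit diagonal, rank at
most 2, and with trace exactly N. Its two nonzero eigenvalues therefore sum
to N, so the leading one is always at least N/2 — the leading eigenvector
captures at least half of the total variance of every volume. That rank-2
structure also gives a closed-form eigensolution via the 2 x 2 Gram matrix of
``[c, s]``, which is what :func:`leading_eigen_series` uses.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import linalg, signal as sps

from .records import ScanRecord

__all__ = [
    "PhaseSeries",
    "LeadingEigenSeries",
    "hilbert_phase",
    "trim_edge_artifact",
    "phase_coherence_volume",
    "leading_eigenvector",
    "leading_eigen_series",
    "reconstruct_outer",
    "collapse_time",
    "static_network",
    "eigenseries_from_scan",
    "n_unique_edges",
    "EDGE_TRIM_DEFAULT",
]

#: Volumes removed from each end of a scan after the Hilbert transform, which
#: distorts phase estimates at the series boundaries.
EDGE_TRIM_DEFAULT = 5


@dataclass
class PhaseSeries:
    """Instantaneous phases, ``theta`` of shape (n_volumes, n_nodes), wrapped
    to (-pi, pi]; carries the provenance labels of the source scan."""

    theta: np.ndarray
    tr_seconds: float
    subject_id: str
    session_id: str
    task: str

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.ndim != 2:
            raise ValueError("theta must be (n_volumes, n_nodes)")
        if not np.all(np.isfinite(self.theta)):
            raise ValueError("theta contains non-finite entries")

    @property
    def n_volumes(self) -> int:
        return self.theta.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.theta.shape[1]

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.subject_id, self.session_id, self.task)


@dataclass
class LeadingEigenSeries:
    """Per-volume leading eigenvectors of the phase-coherence matrices.

    ``v1`` has shape (n_volumes, n_nodes); each row is a unit-norm eigenvector
    with its largest-magnitude entry made positive (a serialization
    convention — downstream similarity uses absolute correlation, so the sign
    never affects results). ``lambda1`` holds the leading eigenvalues and
    ``variance_fraction = lambda1 / n_nodes`` the fraction of total variance
    (trace) each eigenvector captures, always in [0.5, 1].
    """

    v1: np.ndarray
    lambda1: np.ndarray
    variance_fraction: np.ndarray
    tr_seconds: float
    subject_id: str
    session_id: str
    task: str

    def __post_init__(self) -> None:
        self.v1 = np.asarray(self.v1, dtype=float)
        self.lambda1 = np.asarray(self.lambda1, dtype=float)
        self.variance_fraction = np.asarray(self.variance_fraction, dtype=float)
        if self.v1.ndim != 2:
            raise ValueError("v1 must be (n_volumes, n_nodes)")
        if self.lambda1.shape != (self.v1.shape[0],):
            raise ValueError("lambda1 must have one entry per volume")
        if self.variance_fraction.shape != (self.v1.shape[0],):
            raise ValueError("variance_fraction must have one entry per volume")

    @property
    def n_volumes(self) -> int:
        return self.v1.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.v1.shape[1]

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.subject_id, self.session_id, self.task)

    def truncate(self, n_volumes: int) -> "LeadingEigenSeries":
        """Keep only the first ``n_volumes`` volumes."""
        if not (0 < n_volumes <= self.n_volumes):
            raise ValueError("invalid truncation length")
        return dataclasses.replace(
            self,
            v1=self.v1[:n_volumes],
            lambda1=self.lambda1[:n_volumes],
            variance_fraction=self.variance_fraction[:n_volumes],
        )


def n_unique_edges(n_nodes: int) -> int:
    """Number of unique (upper-triangle) edges of an N-node network."""
    return n_nodes * (n_nodes - 1) // 2


def hilbert_phase(scan: ScanRecord) -> PhaseSeries:
    """Instantaneous phase of every node series via the analytic signal.

    Expects band-limited, (near) zero-mean input; each node series is
    demeaned defensively before the transform. A constant node series has no
    defined phase and raises, naming the offending node.
    """
    sd = scan.data.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(
            f"constant (zero-variance) node series: node index {dead[0]}"
        )
    centered = scan.data - scan.data.mean(axis=0, keepdims=True)
    analytic = sps.hilbert(centered, axis=0)
    return PhaseSeries(
        theta=np.angle(analytic),
        tr_seconds=scan.tr_seconds,
        subject_id=scan.subject_id,
        session_id=scan.session_id,
        task=scan.task,
    )


def trim_edge_artifact(series, k: int = EDGE_TRIM_DEFAULT):
    """Drop the first and last ``k`` volumes (Hilbert boundary artifact).

    Accepts a :class:`PhaseSeries`, a :class:`LeadingEigenSeries`, or a plain
    per-volume array (e.g. motion flags), and returns the same type.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if isinstance(series, PhaseSeries):
        if series.n_volumes <= 2 * k:
            raise ValueError(f"{series.n_volumes} volumes <= 2*{k}, nothing left")
        return dataclasses.replace(series, theta=series.theta[k : series.n_volumes - k])
    if isinstance(series, LeadingEigenSeries):
        if series.n_volumes <= 2 * k:
            raise ValueError(f"{series.n_volumes} volumes <= 2*{k}, nothing left")
        sl = slice(k, series.n_volumes - k)
        return dataclasses.replace(
            series,
            v1=series.v1[sl],
            lambda1=series.lambda1[sl],
            variance_fraction=series.variance_fraction[sl],
        )
    arr = np.asarray(series)
    if arr.shape[0] <= 2 * k:
        raise ValueError(f"{arr.shape[0]} volumes <= 2*{k}, nothing left")
    return arr[k : arr.shape[0] - k] if k else arr


def phase_coherence_volume(theta_t: np.ndarray) -> np.ndarray:
    """Coherence matrix of one volume: entry (i, j) = cos(theta_i - theta_j)."""
    theta_t = np.asarray(theta_t, dtype=float)
    if theta_t.ndim != 1:
        raise ValueError("theta_t must be a 1-D phase vector")
    if not np.all(np.isfinite(theta_t)):
        raise ValueError("phases must be finite")
    return np.cos(theta_t[:, None] - theta_t[None, :])


def _fix_sign(v: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude entry positive (deterministic orientation)."""
    i = int(np.argmax(np.abs(v)))
    return -v if v[i] < 0 else v


def leading_eigenvector(vol: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Leading eigenpair of a coherence matrix by dense symmetric solve.

    Returns ``(v1, lambda1, variance_fraction)`` with ``v1`` unit-norm,
    sign-fixed, and ``variance_fraction = lambda1 / trace``. The matrix is
    PSD, so the largest algebraic eigenvalue is also the largest in
    magnitude.
    """
    vol = np.asarray(vol, dtype=float)
    n = vol.shape[0]
    if vol.shape != (n, n):
        raise ValueError("volume must be square")
    w, v = linalg.eigh(vol, subset_by_index=[n - 1, n - 1])
    lam1 = float(w[0])
    v1 = _fix_sign(v[:, 0])
    trace = float(np.trace(vol))
    return v1, lam1, lam1 / trace


def leading_eigen_series(phases: PhaseSeries) -> LeadingEigenSeries:
    """Leading eigenpair of every volume via the rank-2 closed form.

    Each coherence matrix equals ``c c^T + s s^T`` (c = cos(theta_t),
    s = sin(theta_t)), so its nonzero spectrum equals that of the 2 x 2 Gram
    matrix ``[[c.c, c.s], [c.s, s.s]]`` and its eigenvectors lie in
    span{c, s}. This avoids ever materialising the N x N matrices; it is
    algebraically exact, not an approximation.
    """
    c = np.cos(phases.theta)  # (T, N)
    s = np.sin(phases.theta)
    a = np.einsum("tn,tn->t", c, c)
    b = np.einsum("tn,tn->t", c, s)
    d = np.einsum("tn,tn->t", s, s)
    # eigenvalues of [[a, b], [b, d]]
    half_trace = 0.5 * (a + d)
    radius = np.sqrt(0.25 * (a - d) ** 2 + b**2)
    lam1 = half_trace + radius
    # eigenvector (w0, w1) of the 2x2; guard the degenerate b=0 branch
    w0 = np.where(np.abs(b) > 0, lam1 - d, np.where(a >= d, 1.0, 0.0))
    w1 = np.where(np.abs(b) > 0, b, np.where(a >= d, 0.0, 1.0))
    v = w0[:, None] * c + w1[:, None] * s
    norms = np.linalg.norm(v, axis=1, keepdims=True)
    # norm can only vanish in exactly-degenerate cases; fall back to c
    bad = np.flatnonzero(norms[:, 0] < 1e-12)
    for t in bad:
        v[t] = c[t]
        norms[t, 0] = np.linalg.norm(c[t])
    v /= norms
    # sign convention: largest-|entry| positive, per volume
    idx = np.argmax(np.abs(v), axis=1)
    signs = np.sign(v[np.arange(v.shape[0]), idx])
    v *= signs[:, None]
    n = phases.n_nodes
    return LeadingEigenSeries(
        v1=v,
        lambda1=lam1,
        variance_fraction=lam1 / n,
        tr_seconds=phases.tr_seconds,
        subject_id=phases.subject_id,
        session_id=phases.session_id,
        task=phases.task,
    )


def reconstruct_outer(v1: np.ndarray, lambda1: float | None = None) -> np.ndarray:
    """Rank-1 reconstruction of a coherence volume from its leading eigenvector.

    With ``lambda1`` supplied the result is ``lambda1 * v1 v1^T`` — the best
    rank-1 approximation of the volume in the Frobenius sense (error bounded
    by the second eigenvalue). Without it, the raw outer product ``v1 v1^T``
    is returned. The pipeline's temporal collapse uses the eigenvalue-scaled
    form. A sign flip of ``v1`` leaves the result unchanged.
    """
    v1 = np.asarray(v1, dtype=float)
    outer = np.outer(v1, v1)
    return outer if lambda1 is None else lambda1 * outer


def collapse_time(
    series: LeadingEigenSeries | np.ndarray,
    lambda1: np.ndarray | None = None,
    weighted: bool = True,
) -> np.ndarray:
    """Sum of per-volume rank-1 reconstructions across time.

    For a :class:`LeadingEigenSeries` the eigenvalue-weighted sum
    ``sum_t lambda1(t) v1(t) v1(t)^T`` is the default; it preserves each
    volume's energy, so the collapsed matrix tracks the scan's static
    (Pearson) network. Pass ``weighted=False`` for the unweighted sum of raw
    outer products.
    """
    if isinstance(series, LeadingEigenSeries):
        v = series.v1
        lam = series.lambda1
    else:
        v = np.asarray(series, dtype=float)
        if v.ndim != 2:
            raise ValueError("series must be (n_volumes, n_nodes)")
        lam = lambda1
    if v.shape[0] == 0:
        raise ValueError("cannot collapse an empty series")
    if weighted:
        if lam is None:
            raise ValueError("weighted collapse requires eigenvalues")
        return (v.T * np.asarray(lam)) @ v
    return v.T @ v


def static_network(scan: ScanRecord) -> np.ndarray:
    """Static functional network: Pearson correlation of node time series."""
    if scan.n_volumes < 3:
        raise ValueError("static network needs at least 3 volumes")
    sd = scan.data.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(
            f"constant (zero-variance) node series: node index {dead[0]}"
        )
    return np.corrcoef(scan.data, rowvar=False)


def eigenseries_from_scan(
    scan: ScanRecord, trim: int = EDGE_TRIM_DEFAULT
) -> LeadingEigenSeries:
    """Scan -> phases -> edge trim -> per-volume leading eigenvectors."""
    phases = trim_edge_artifact(hilbert_phase(scan), trim)
    return leading_eigen_series(phases)
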