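"""Per-session preprocessing of region-level BOLD time series.

The pipeline starts from region x time matrices (voxel-level spatial
preprocessing is assumed done upstream).  Three operations remain before
connectivity estimation: discarding initial equilibration volumes,
motion-based session exclusion, and band-pass filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Optional

import numpy as np

#: Exclusion limits for per-session head motion, relative to the first
#: volume: translations in millimetres, rotations in radians.
TRANSLATION_LIMIT_MM = 2.0
ROTATION_LIMIT_RAD = 0.02


@dataclass
class SessionSeries:
    """One session's region x time BOLD matrix plus sampling metadata.

    ``data`` has shape (n_regions, n_timepoints).
    """

    data: np.ndarray
    tr_seconds: float
    subject_id: str = ""
    session_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("session data must be a 2-D region x time matrix")
        if self.data.shape[0] < 2:
            raise ValueError("need at least 2 regions")
        if self.data.shape[1] < 8:
            raise ValueError("need at least 8 time points")
        if not np.isfinite(self.data).all():
            raise ValueError("session data contains non-finite values")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    @property
    def nyquist_hz(self) -> float:
        return 1.0 / (2.0 * self.tr_seconds)


@dataclass
class MotionTrace:
    """Rigid-body realignment parameters: per-volume translations (mm)
    and rotations (rad), each of shape (n_volumes, 3)."""

    translations: np.ndarray
    rotations: np.ndarray

    def __post_init__(self) -> None:
        self.translations = np.asarray(self.translations, dtype=float)
        self.rotations = np.asarray(self.rotations, dtype=float)
        for name, arr in (("translations", self.translations), ("rotations", self.rotations)):
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValueError(f"{name} must have shape (n_volumes, 3)")
        if self.translations.shape[0] != self.rotations.shape[0]:
            raise ValueError("translations and rotations must cover the same volumes")
        if self.translations.shape[0] == 0:
            raise ValueError("motion trace is empty")

    @property
    def n_volumes(self) -> int:
        return self.translations.shape[0]


@dataclass(frozen=True)
class QCResult:
    passed: bool
    reason: Optional[str]
    max_translation_mm: float
    max_rotation_rad: float


def qc_session(motion: MotionTrace) -> QCResult:
    """Decide whether a session survives the motion criterion.

    Displacements are measured relative to the session's first volume (the
    realignment-parameter convention).  A session fails when the maximum
    absolute displacement reaches 2 mm of translation or 0.02 rad of
    rotation on any axis; both limits are inclusive.
    """
    if not (np.isfinite(motion.translations).all() and np.isfinite(motion.rotations).all()):
        raise ValueError("motion trace contains missing or non-finite values")
    dt = motion.translations - motion.translations[0]
    dr = motion.rotations - motion.rotations[0]
    max_t = float(np.abs(dt).max())
    max_r = float(np.abs(dr).max())
    reasons = []
    if max_t >= TRANSLATION_LIMIT_MM:
        reasons.append(f"translation {max_t:.3f} mm >= {TRANSLATION_LIMIT_MM} mm")
    if max_r >= ROTATION_LIMIT_RAD:
        reasons.append(f"rotation {max_r:.4f} rad >= {ROTATION_LIMIT_RAD} rad")
    return QCResult(
        passed=not reasons,
        reason="; ".join(reasons) or None,
        max_translation_mm=max_t,
        max_rotation_rad=max_r,
    )


def discard_initial_volumes(series: SessionSeries, k: int = 3) -> SessionSeries:
    """Drop the first ``k`` volumes (T1-equilibration convention)."""
    if k < 0:
        raise ValueError("k must be non-negative")
    if k >= series.n_timepoints:
        raise ValueError(
            f"cannot discard {k} volumes from a {series.n_timepoints}-volume session"
        )
    if k == 0:
        return replace(series, data=series.data.copy())
    return replace(series, data=series.data[:, k:].copy())


@lru_cache(maxsize=8)
def _bandtrend_projector(t: int, tr: float, low_hz: float, high_hz: float) -> np.ndarray:
    """Orthogonal projector onto signals that are band-limited to
    [low_hz, high_hz] AND orthogonal to constant offset and linear trend.

    The in-band discrete Fourier modes (cos/sin pairs at the kept bins)
    span the band subspace B; the intersection with the trend-free
    subspace is {B c : L^T B c = 0} for L = span{1, t}, whose basis is B
    times the null space of L^T B.  The resulting projector is symmetric
    and exactly idempotent.
    """
    n = np.arange(t)
    freqs = np.fft.rfftfreq(t, d=tr)
    keep = np.flatnonzero((freqs >= low_hz) & (freqs <= high_hz))
    cols = []
    for k in keep:
        c = np.cos(2.0 * np.pi * k * n / t)
        cols.append(c / np.linalg.norm(c))
        if k != 0 and not (t % 2 == 0 and k == t // 2):
            s = np.sin(2.0 * np.pi * k * n / t)
            cols.append(s / np.linalg.norm(s))
    if not cols:
        return np.zeros((t, t))
    b = np.column_stack(cols)
    trend = np.column_stack([np.ones(t), n - n.mean()])
    lq, _ = np.linalg.qr(trend)
    constraints = lq.T @ b
    _, sv, vt = np.linalg.svd(constraints, full_matrices=True)
    rank = int((sv > 1e-12).sum())
    null_basis = vt[rank:].T
    w = b @ null_basis
    return w @ w.T


def bandpass(
    series: SessionSeries, low_hz: float = 0.01, high_hz: float = 0.1
) -> SessionSeries:
    """Band-pass filter each region's series to [low_hz, high_hz].

    The filter is the orthogonal projection onto signals that are both
    band-limited (discrete Fourier coefficients outside the pass band
    zeroed) and free of constant offset and linear trend.  Because it is
    a single orthogonal projection, filtering is exactly idempotent and
    output means are ~0 per region.
    """
    if low_hz < 0:
        raise ValueError("low_hz must be non-negative")
    nyq = series.nyquist_hz
    if high_hz > nyq + 1e-12:
        raise ValueError(
            f"high_hz={high_hz} exceeds the Nyquist frequency {nyq:.6g} Hz "
            f"for TR={series.tr_seconds} s"
        )
    if low_hz >= high_hz:
        raise ValueError("low_hz must be below high_hz")
    proj = _bandtrend_projector(
        series.n_timepoints, float(series.tr_seconds), float(low_hz), float(high_hz)
    )
    return replace(series, data=series.data @ proj)
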