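"""Session time series -> subject-level Z matrix -> binary adjacency.

Pairwise Pearson correlations are converted to t values using an
autocorrelation-corrected effective sample size, then to two-sided-
consistent standard-normal Z scores.  Session Z matrices are averaged per
subject and binarized at a fixed threshold (default Z > 1.96, i.e.
p < 0.05 two-sided) to give the adjacency matrix of the connectome graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import special, stats

from .preprocess import SessionSeries

DEFAULT_Z_THRESHOLD = 1.96
DEFAULT_Z_CAP = 40.0

ESS_MODES = ("lag1", "full")


class SubjectExcludedError(RuntimeError):
    """Raised when a subject has no usable (QC-passing) sessions."""


@dataclass
class ZMatrix:
    """Symmetric region x region matrix of connectivity Z scores.

    The diagonal is stored as 0 (self-connectivity is undefined).
    """

    z: np.ndarray
    n_sessions_used: int = 1
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.ndim != 2 or self.z.shape[0] != self.z.shape[1]:
            raise ValueError("Z matrix must be square")
        if not np.isfinite(self.z).all():
            raise ValueError("Z matrix contains non-finite values")
        if not np.allclose(self.z, self.z.T, atol=1e-10):
            raise ValueError("Z matrix must be symmetric")

    @property
    def n_regions(self) -> int:
        return self.z.shape[0]


@dataclass
class Adjacency:
    """Binary symmetric adjacency matrix with zero diagonal."""

    a: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a)
        if self.a.ndim != 2 or self.a.shape[0] != self.a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(self.a, self.a.T):
            raise ValueError("adjacency must be symmetric")
        vals = np.unique(self.a)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("adjacency entries must be 0/1")
        if np.any(np.diag(self.a) != 0):
            raise ValueError("adjacency diagonal must be zero")
        self.a = self.a.astype(np.int8)

    @property
    def n_regions(self) -> int:
        return self.a.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.a.sum()) // 2

    def degrees(self) -> np.ndarray:
        return self.a.sum(axis=1).astype(float)


def pearson_matrix(series: SessionSeries) -> np.ndarray:
    """Region x region Pearson correlation matrix of one session."""
    if series.n_timepoints < 4:
        raise ValueError("need at least 4 time points for correlation")
    sd = series.data.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(f"zero-variance region(s): {dead.tolist()}")
    r = np.corrcoef(series.data)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return r


def lag1_autocorr(series: SessionSeries) -> np.ndarray:
    """Per-region sample autocorrelation at lag 1."""
    if series.n_timepoints < 4:
        raise ValueError("need at least 4 time points")
    x = series.data
    sd = x.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(f"zero-variance region(s): {dead.tolist()}")
    xc = x - x.mean(axis=1, keepdims=True)
    num = (xc[:, 1:] * xc[:, :-1]).sum(axis=1)
    den = (xc**2).sum(axis=1)
    return np.clip(num / den, -1.0, 1.0)


def autocorr_function(series: SessionSeries, max_lag: int | None = None) -> np.ndarray:
    """Per-region sample autocorrelation function.

    Returns shape (n_regions, max_lag) for lags 1..max_lag; the default
    truncation is n_timepoints // 4.
    """
    x = series.data
    t = series.n_timepoints
    if max_lag is None:
        max_lag = t // 4
    max_lag = int(min(max_lag, t - 2))
    xc = x - x.mean(axis=1, keepdims=True)
    den = (xc**2).sum(axis=1)
    out = np.empty((series.n_regions, max_lag))
    for k in range(1, max_lag + 1):
        out[:, k - 1] = (xc[:, k:] * xc[:, :-k]).sum(axis=1) / den
    return np.clip(out, -1.0, 1.0)


def effective_n(n_timepoints, rho_i, rho_j, floor: float = 4.0):
    """Autocorrelation-corrected effective sample size (lag-1 form).

    N_eff = n (1 - rho_i rho_j) / (1 + rho_i rho_j), floored so the t
    distribution keeps at least 2 degrees of freedom.  Scalar or array
    inputs broadcast.
    """
    rho_i = np.asarray(rho_i, dtype=float)
    rho_j = np.asarray(rho_j, dtype=float)
    prod = rho_i * rho_j
    if np.any(prod <= -1.0):
        raise ValueError("rho_i * rho_j = -1 is degenerate")
    neff = n_timepoints * (1.0 - prod) / (1.0 + prod)
    return np.maximum(neff, floor)


def effective_n_full(n_timepoints, acf_i, acf_j, floor: float = 4.0):
    """Full-lag effective sample size N_eff = n / (1 + 2 sum_k rho_i(k) rho_j(k)).

    ``acf_i``/``acf_j`` hold autocorrelations at lags 1..K (last axis).
    The denominator is floored at 0.05 to guard against negative estimated
    sums; the result is floored like the lag-1 form.
    """
    acf_i = np.asarray(acf_i, dtype=float)
    acf_j = np.asarray(acf_j, dtype=float)
    denom = 1.0 + 2.0 * (acf_i * acf_j).sum(axis=-1)
    denom = np.maximum(denom, 0.05)
    return np.maximum(n_timepoints / denom, floor)


def r_to_z(r, n_eff, cap: float = DEFAULT_Z_CAP):
    """Convert correlations to Z scores through the t distribution.

    t = r sqrt((N_eff - 2)/(1 - r^2)); Z is the standard-normal quantile
    matching the t upper-tail probability, evaluated in log space so large
    |t| does not underflow.  sign(Z) = sign(r).  |r| = 1 returns ``cap``
    (with the sign of r) and emits a warning.
    """
    r = np.asarray(r, dtype=float)
    n_eff = np.broadcast_to(np.asarray(n_eff, dtype=float), r.shape).copy()
    if np.any(n_eff < 4):
        raise ValueError("n_eff must be >= 4")
    sat = np.abs(r) >= 1.0
    if np.any(sat):
        warnings.warn(
            f"|r| = 1 encountered; Z capped at {cap}", RuntimeWarning, stacklevel=2
        )
    rs = np.where(sat, 0.0, r)
    df = n_eff - 2.0
    t = rs * np.sqrt(df / (1.0 - rs**2))
    z = -special.ndtri_exp(stats.t.logsf(np.abs(t), df))
    z = np.minimum(np.abs(z), cap)  # tail probabilities below ~exp(-800) saturate
    z = np.sign(rs) * z
    z = np.where(sat, np.sign(r) * cap, z)
    if z.ndim == 0:
        return float(z)
    return z


def session_zmatrix(
    series: SessionSeries,
    ess_mode: str = "lag1",
    z_cap: float = DEFAULT_Z_CAP,
) -> ZMatrix:
    """Compute one session's region x region Z matrix."""
    if ess_mode not in ESS_MODES:
        raise ValueError(f"ess_mode must be one of {ESS_MODES}")
    r = pearson_matrix(series)
    n = series.n_timepoints
    if ess_mode == "lag1":
        rho = lag1_autocorr(series)
        neff = effective_n(n, rho[:, None], rho[None, :])
    else:
        acf = autocorr_function(series)
        neff = effective_n_full(n, acf[:, None, :], acf[None, :, :])
    np.fill_diagonal(r, 0.0)  # diagonal is not a connection
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        z = r_to_z(r, neff, cap=z_cap)
    z = (z + z.T) / 2.0
    np.fill_diagonal(z, 0.0)
    return ZMatrix(z=z, n_sessions_used=1, subject_id=series.subject_id)


def average_z(z_list: Sequence[ZMatrix]) -> ZMatrix:
    """Element-wise mean of the session Z matrices that passed QC."""
    z_list = list(z_list)
    if not z_list:
        raise SubjectExcludedError("no usable sessions (all failed QC)")
    shape = z_list[0].z.shape
    for zm in z_list[1:]:
        if zm.z.shape != shape:
            raise ValueError("session Z matrices have mismatched shapes")
    mean = np.mean([zm.z for zm in z_list], axis=0)
    return ZMatrix(
        z=mean, n_sessions_used=len(z_list), subject_id=z_list[0].subject_id
    )


def binarize(z: ZMatrix, threshold: float = DEFAULT_Z_THRESHOLD) -> Adjacency:
    """Adjacency a[i,j] = 1 iff z[i,j] > threshold (strict), i != j."""
    a = (z.z > threshold).astype(np.int8)
    np.fill_diagonal(a, 0)
    return Adjacency(a=a, subject_id=z.subject_id)


def subject_adjacency(
    sessions: Iterable[SessionSeries],
    threshold: float = DEFAULT_Z_THRESHOLD,
    ess_mode: str = "lag1",
    z_cap: float = DEFAULT_Z_CAP,
) -> tuple[ZMatrix, Adjacency]:
    """Convenience: session series -> averaged Z matrix -> adjacency."""
    zs = [session_zmatrix(s, ess_mode=ess_mode, z_cap=z_cap) for s in sessions]
    zbar = average_z(zs)
    return zbar, binarize(zbar, threshold=threshold)
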