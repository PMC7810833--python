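"""Normalized alpha-centrality (nAC) of a binary connectome graph.

Given adjacency matrix A, the alpha-centrality matrix is the partial sum

    C_an = A + a A^2 + a^2 A^3 + ... + a^n A^(n+1)

normalized by the sum of all its elements; a region's score is the row
sum of the normalized matrix, so all scores sum to 1.  At alpha = 0 the
score is exactly degree / total degree (degree centrality); at
alpha = 1/lambda (lambda the dominant eigenvalue of A) the normalized
quantity approaches the dominant-eigenvector profile as the series order
grows (eigenvector centrality).  The default order n = 20 follows the
convergence of the normalized scores at connectome scale; the residual
deviation from the infinite-order limit decays like 1/n because the
leading term of the series grows linearly while the sub-dominant part
saturates (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.sparse import csr_matrix

from .connectivity import Adjacency

DEFAULT_ORDER = 20


@dataclass
class CentralityProfile:
    """Per-region nAC scores for one subject.

    ``nac0``/``nac1`` are on the canonical scale (each sums to 1) and feed
    all statistics; ``nac0_rescaled``/``nac1_rescaled`` divide by the
    maximum (max exactly 1) and are intended for distribution histograms.
    ``nac1`` is ``None`` when the graph has no edges (lambda = 0).
    """

    subject_id: str
    nac0: np.ndarray
    nac1: Optional[np.ndarray]
    lambda_max: float
    order_n: int
    is_connected: bool

    @property
    def nac0_rescaled(self) -> np.ndarray:
        return self.nac0 / self.nac0.max()

    @property
    def nac1_rescaled(self) -> Optional[np.ndarray]:
        if self.nac1 is None:
            return None
        return self.nac1 / self.nac1.max()

    @property
    def n_regions(self) -> int:
        return self.nac0.shape[0]


def dominant_eigenvalue(a: Adjacency, tol: float = 1e-10) -> float:
    """Largest eigenvalue of the adjacency matrix (symmetric spectrum)."""
    if a.n_edges == 0:
        return 0.0
    w = np.linalg.eigvalsh(a.a.astype(float))
    lam = float(w[-1])
    return 0.0 if lam < tol else lam


def alpha_centrality_series(
    a: Adjacency | np.ndarray,
    alpha: float,
    order_n: int = DEFAULT_ORDER,
    *,
    lambda_max: float | None = None,
) -> np.ndarray:
    """Exact partial sum C_an = sum_{k=0..n} alpha^k A^(k+1).

    Accumulated by iterated multiplication (P <- alpha P A starting from
    P = A), which is exact for the stated series and keeps the output
    symmetric for symmetric input.  ``lambda_max`` may be supplied to
    skip recomputing the spectrum for the alpha <= 1/lambda check.
    """
    A = a.a if isinstance(a, Adjacency) else np.asarray(a)
    A = A.astype(float)
    if order_n < 1:
        raise ValueError("order_n must be >= 1")
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    if alpha == 0:
        return A.copy()  # every higher term vanishes
    lam = float(np.linalg.eigvalsh(A)[-1]) if lambda_max is None else lambda_max
    if lam > 0 and alpha > 1.0 / lam + 1e-12:
        raise ValueError(
            f"alpha={alpha} exceeds 1/lambda={1.0 / lam:.6g}; the normalized "
            "series is only defined for 0 <= alpha <= 1/lambda"
        )
    P = A.copy()
    S = A.copy()
    for _ in range(order_n):
        P = alpha * (P @ A)
        S += P
    return S


def nac_scores(
    a: Adjacency | np.ndarray,
    alpha: float,
    order_n: int = DEFAULT_ORDER,
    *,
    lambda_max: float | None = None,
) -> np.ndarray:
    """Per-region nAC score vector: row sums of C_an / sum(C_an)."""
    C = alpha_centrality_series(a, alpha, order_n, lambda_max=lambda_max)
    total = C.sum()
    if total == 0:
        raise ValueError("empty graph: alpha-centrality series is all zero")
    return C.sum(axis=1) / total


def compute_profile(
    a: Adjacency, order_n: int = DEFAULT_ORDER, subject_id: str | None = None
) -> CentralityProfile:
    """nAC0 (alpha = 0) and nAC1 (alpha = 1/lambda) for one adjacency.

    With no edges, lambda = 0 and nAC1 is undefined; the profile carries
    ``nac1 = None`` and the subject should be flagged downstream.
    """
    sid = subject_id if subject_id is not None else a.subject_id
    lam = dominant_eigenvalue(a)
    n_comp, _ = connected_components(csr_matrix(a.a), directed=False)
    if lam == 0.0:
        if a.n_edges == 0:
            raise ValueError("graph has no edges; nAC is undefined")
    nac0 = nac_scores(a, 0.0, order_n)
    nac1 = (
        nac_scores(a, 1.0 / lam, order_n, lambda_max=lam) if lam > 0 else None
    )
    return CentralityProfile(
        subject_id=sid,
        nac0=nac0,
        nac1=nac1,
        lambda_max=lam,
        order_n=order_n,
        is_connected=(n_comp == 1),
    )
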