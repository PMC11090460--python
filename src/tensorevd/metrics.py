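"""Approximation-quality and dimension-reduction metrics.

Two complementary dissimilarities between a kernel ``K`` and a low-rank
reconstruction ``K_alpha = V D V'``: the Frobenius norm of the difference
(scale-dependent, comparable only at fixed n) and the correlation matrix
distance ``CMD(A, B) = 1 - tr(AB) / (‖A‖_F ‖B‖_F)``, which is scale
invariant and lies in [0, 1] for PSD inputs (0 iff the matrices are
proportional, 1 for orthogonal supports).  Plus the effective-rank count
used when comparing basis sizes between methods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import EVDResult, Kernel, reconstruct

__all__ = [
    "ApproxReport",
    "frobenius_distance",
    "cmd",
    "rank_count",
    "compare_bases",
]


class UndefinedMetricError(ValueError):
    """Metric is undefined for the given input (e.g. an all-zero matrix)."""


def _as_array(A) -> np.ndarray:
    return A.values if isinstance(A, Kernel) else np.asarray(A, dtype=float)


def frobenius_distance(A, B) -> float:
    """``sqrt(sum((A - B)**2))``; zero iff A equals B."""
    A, B = _as_array(A), _as_array(B)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {B.shape}")
    return float(np.linalg.norm(A - B, "fro"))


def cmd(A, B) -> float:
    """Correlation matrix distance ``1 - tr(AB) / (‖A‖_F ‖B‖_F)``.

    For symmetric A, B, ``tr(AB) = sum(A * B)`` elementwise.  Raises
    :class:`UndefinedMetricError` if either matrix is all zero.
    """
    A, B = _as_array(A), _as_array(B)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {B.shape}")
    na = np.linalg.norm(A, "fro")
    nb = np.linalg.norm(B, "fro")
    if na == 0.0 or nb == 0.0:
        raise UndefinedMetricError("CMD is undefined for an all-zero matrix")
    return float(1.0 - np.sum(A * B) / (na * nb))


def rank_count(values, rel_tol: float | None = None) -> int:
    """Number of eigenvalues deemed positive.

    ``values`` must be sorted descending.  The cutoff is relative to the
    largest value; the default ``rel_tol = 1e-10 * len(values)`` grows with
    dimension, mirroring how accumulated roundoff scales.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0 or values[0] <= 0.0:
        return 0
    if rel_tol is None:
        rel_tol = 1e-10 * len(values)
    return int(np.sum(values > rel_tol * values[0]))


@dataclass
class ApproxReport:
    """Approximation quality of one eigen basis against a target kernel."""

    frobenius_distance: float
    cmd: float
    n_vectors: int
    rank_K: int
    alpha_achieved: float
    degenerate: bool = False  # True when CMD was undefined and reported as 1


def _report(K: np.ndarray, evd: EVDResult, rank_K: int) -> ApproxReport:
    Khat = reconstruct(evd)
    fro = frobenius_distance(K, Khat)
    try:
        d = cmd(K, Khat)
        degenerate = False
    except UndefinedMetricError:
        d = 1.0
        degenerate = True
    return ApproxReport(
        frobenius_distance=fro,
        cmd=d,
        n_vectors=evd.n_vectors,
        rank_K=rank_K,
        alpha_achieved=evd.alpha_achieved,
        degenerate=degenerate,
    )


def compare_bases(K, evd_a: EVDResult, evd_b: EVDResult) -> tuple[ApproxReport, ApproxReport]:
    """Score two bases (e.g. direct eigen vs tensor-EVD) against the same kernel."""
    Kv = _as_array(K)
    if evd_a.n != Kv.shape[0] or evd_b.n != Kv.shape[0]:
        raise ValueError(
            f"basis row counts ({evd_a.n}, {evd_b.n}) do not match kernel size {Kv.shape[0]}"
        )
    eigvals = np.linalg.eigvalsh(Kv)[::-1]
    rk = rank_count(np.clip(eigvals, 0.0, None))
    return _report(Kv, evd_a, rk), _report(Kv, evd_b, rk)
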