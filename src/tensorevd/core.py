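"""Eigen-factorization of Hadamard-product covariance matrices.

A genotype-by-environment interaction kernel has the form

    K = (Z1 K1 Z1') ∘ (Z2 K2 Z2')

where ``K1`` (n1 x n1) and ``K2`` (n2 x n2) are positive semidefinite
relationship matrices (e.g. a genomic relationship matrix over hybrids and
an environmental relationship matrix over trial environments), ``Z1`` and
``Z2`` are 0/1 incidence matrices mapping the n observations to rows of each
kernel, and ``∘`` is the elementwise (Hadamard) product.  ``K`` is an n x n
submatrix of the Kronecker product ``K1 ⊗ K2``, whose eigenpairs are the
pairwise products of the factor eigenpairs.  The tensor-EVD algorithm
exploits this: it eigendecomposes the two small kernels, forms candidate
basis vectors as elementwise products of observation-indexed factor
eigenvectors, renormalizes them to unit norm, and truncates the candidate
list once a target fraction ``alpha`` of ``trace(K)`` is captured — without
ever forming the n x n matrix ``K``.

The module also provides the exact ingredients used as testing oracles:
a plain symmetric eigendecomposition (:func:`eigen_sym`), the explicit
Hadamard-product matrix (:func:`hadamard_kernel`), and the exact Kronecker
eigendecomposition (:func:`kronecker_evd`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

logger = logging.getLogger(__name__)

__all__ = [
    "Kernel",
    "EVDResult",
    "InvalidKernelError",
    "NotPositiveSemidefiniteError",
    "LabelResolutionError",
    "DesignError",
    "eigen_sym",
    "hadamard_kernel",
    "kronecker_evd",
    "tensor_evd",
    "reconstruct",
    "truncate_evd",
    "resolve_labels",
]

SYMMETRY_RTOL = 1e-10
DEFAULT_CLAMP_TOL = 1e-8


class InvalidKernelError(ValueError):
    """Input matrix is not a valid kernel (non-square, asymmetric, bad labels)."""


class NotPositiveSemidefiniteError(InvalidKernelError):
    """Kernel has an eigenvalue more negative than the clamping tolerance allows."""


class LabelResolutionError(KeyError):
    """An ID entry does not occur among the kernel's labels."""


class DesignError(ValueError):
    """Observation-to-kernel ID vectors are inconsistent."""


@dataclass
class Kernel:
    """A labeled symmetric positive semidefinite matrix.

    Parameters
    ----------
    values
        Square array of covariance/similarity entries.
    labels
        One unique identifier per row/column, in order.

    Symmetry is validated at construction (relative tolerance
    ``1e-10 * max(1, max|K|)``); positive semidefiniteness is enforced when
    the kernel is eigendecomposed, where eigenvalues mildly below zero are
    clamped and strongly negative ones raise
    :class:`NotPositiveSemidefiniteError`.
    """

    values: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=str)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise InvalidKernelError(
                f"kernel matrix must be square, got shape {self.values.shape}"
            )
        if self.labels.ndim != 1 or len(self.labels) != self.values.shape[0]:
            raise InvalidKernelError(
                f"expected {self.values.shape[0]} labels, got {len(self.labels)}"
            )
        if len(np.unique(self.labels)) != len(self.labels):
            raise InvalidKernelError("kernel labels must be unique")
        scale = max(1.0, float(np.max(np.abs(self.values))) if self.values.size else 1.0)
        asym = float(np.max(np.abs(self.values - self.values.T))) if self.values.size else 0.0
        if asym > SYMMETRY_RTOL * scale:
            raise InvalidKernelError(
                f"kernel is asymmetric: max |K-K'| = {asym:.3e} exceeds tolerance"
            )
        # exact-symmetrize so downstream eigh sees a clean input
        self.values = 0.5 * (self.values + self.values.T)
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def positions(self, ids) -> np.ndarray:
        """Map a sequence of labels to row/column positions (label -> index)."""
        return resolve_labels(self._index, ids)


def resolve_labels(index: dict, ids) -> np.ndarray:
    ids = np.asarray(ids, dtype=str)
    out = np.empty(len(ids), dtype=np.int64)
    for a, lab in enumerate(ids):
        try:
            out[a] = index[lab]
        except KeyError:
            raise LabelResolutionError(
                f"ID entry {lab!r} (position {a}) not found among kernel labels"
            ) from None
    return out


@dataclass
class EVDResult:
    """A (possibly truncated) eigen basis of a covariance matrix.

    ``vectors`` is n x p with unit-norm columns; ``values`` is length p,
    nonnegative and descending.  ``total_variance`` is the trace of the
    target matrix, so ``alpha_achieved = sum(values) / total_variance``.
    ``source_indices`` records, for bases built from two factor kernels,
    which eigenpair (i of K1, j of K2) produced each column; it is empty for
    direct eigendecompositions.
    """

    vectors: np.ndarray
    values: np.ndarray
    total_variance: float
    alpha_requested: float = 1.0
    alpha_achieved: float = 1.0
    source_indices: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=np.int64))

    @property
    def n(self) -> int:
        return self.vectors.shape[0]

    @property
    def n_vectors(self) -> int:
        return self.vectors.shape[1]


def _fix_signs(V: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude entry of each column positive (byte-stable output)."""
    if V.size == 0:
        return V
    idx = np.argmax(np.abs(V), axis=0)
    signs = np.sign(V[idx, np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    return V * signs


def eigen_sym(K: Kernel, clamp_tol: float = DEFAULT_CLAMP_TOL) -> EVDResult:
    """Symmetric eigendecomposition with descending eigenvalues.

    Eigenvalues in ``[-clamp_tol * max(values), 0)`` are clamped to zero;
    anything more negative raises :class:`NotPositiveSemidefiniteError`.
    Column signs are fixed so the largest-magnitude entry is positive.
    """
    w, V = scipy.linalg.eigh(K.values)
    w = w[::-1]
    V = V[:, ::-1]
    lam_max = float(w[0]) if w.size else 0.0
    floor = -clamp_tol * max(lam_max, 0.0)
    if w.size and float(w[-1]) < floor:
        raise NotPositiveSemidefiniteError(
            f"smallest eigenvalue {w[-1]:.3e} below PSD tolerance {floor:.3e}"
        )
    # clamp roundoff-scale eigenvalues (of either sign) to exact zero so that
    # "positive eigenvalue" is meaningful for rank accounting downstream
    w = np.clip(w, 0.0, None)
    w[w <= clamp_tol * max(lam_max, 0.0)] = 0.0
    V = _fix_signs(V)
    total = float(np.trace(K.values))
    return EVDResult(
        vectors=V,
        values=w,
        total_variance=total,
        alpha_requested=1.0,
        alpha_achieved=float(w.sum() / total) if total > 0 else 1.0,
    )


def _check_ids(ID1, ID2) -> tuple[np.ndarray, np.ndarray]:
    ID1 = np.asarray(ID1, dtype=str)
    ID2 = np.asarray(ID2, dtype=str)
    if len(ID1) != len(ID2):
        raise DesignError(
            f"ID vectors have unequal lengths ({len(ID1)} vs {len(ID2)})"
        )
    if len(ID1) < 1:
        raise DesignError("design must contain at least one observation")
    return ID1, ID2


def hadamard_kernel(K1: Kernel, K2: Kernel, ID1, ID2) -> Kernel:
    """Explicit n x n Hadamard-product kernel ``(Z1 K1 Z1') ∘ (Z2 K2 Z2')``.

    Entry (a, b) is ``K1[ID1[a], ID1[b]] * K2[ID2[a], ID2[b]]``.  PSD by the
    Schur product theorem.  Intended for oracles and desk-scale comparators;
    the point of :func:`tensor_evd` is to avoid forming this matrix.
    """
    ID1, ID2 = _check_ids(ID1, ID2)
    i1 = K1.positions(ID1)
    i2 = K2.positions(ID2)
    values = K1.values[np.ix_(i1, i1)] * K2.values[np.ix_(i2, i2)]
    labels = np.array([f"{a}:{b}#{k}" for k, (a, b) in enumerate(zip(ID1, ID2))])
    return Kernel(values=values, labels=labels)


def _candidate_order(d1: np.ndarray, d2: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All index pairs (i, j) sorted by d1[i]*d2[j] descending, ties (i asc, j asc)."""
    raw = np.outer(d1, d2).ravel()
    # ravel order is already (i asc, j asc): a stable sort keeps that tie order
    order = np.argsort(-raw, kind="stable")
    n2 = len(d2)
    return order // n2, order % n2, raw[order]


def kronecker_evd(K1: Kernel, K2: Kernel, clamp_tol: float = DEFAULT_CLAMP_TOL) -> EVDResult:
    """Exact eigendecomposition of ``K1 ⊗ K2`` from the factor EVDs.

    Eigenvalues are all pairwise products ``d1_i * d2_j`` (descending) and
    eigenvectors the matching Kronecker products ``v1_i ⊗ v2_j``, which are
    orthonormal.  ``total_variance = trace(K1) * trace(K2)``.
    """
    e1 = eigen_sym(K1, clamp_tol)
    e2 = eigen_sym(K2, clamp_tol)
    ii, jj, vals = _candidate_order(e1.values, e2.values)
    n1, n2 = K1.n, K2.n
    V = np.empty((n1 * n2, n1 * n2))
    for k in range(len(vals)):
        V[:, k] = np.kron(e1.vectors[:, ii[k]], e2.vectors[:, jj[k]])
    return EVDResult(
        vectors=V,
        values=vals,
        total_variance=e1.total_variance * e2.total_variance,
        alpha_requested=1.0,
        alpha_achieved=1.0,
        source_indices=np.column_stack([ii, jj]),
    )


def tensor_evd(
    K1: Kernel,
    K2: Kernel,
    ID1,
    ID2,
    alpha: float = 0.95,
    clamp_tol: float = DEFAULT_CLAMP_TOL,
    rescale: bool = True,
    order_by: str = "rescaled",
    block_size: int = 512,
) -> EVDResult:
    """Truncated eigen basis of the Hadamard-product kernel, without forming it.

    Algorithm: eigendecompose ``K1 = V1 D1 V1'`` and ``K2 = V2 D2 V2'``;
    each candidate basis vector is ``w_k = (Z1 v1_i) ∘ (Z2 v2_j)`` — the
    elementwise product of the ID-indexed factor eigenvectors — with raw
    Kronecker eigenvalue ``d~_k = d1_i * d2_j``.  Under replication the
    ``w_k`` are not unit-norm, so each is renormalized,
    ``u_k = w_k / ‖w_k‖``, and (by default) its eigenvalue rescaled to
    ``d*_k = d~_k ‖w_k‖²``; with that rescaling
    ``Σ_k d*_k = trace(K)`` exactly and the full basis reproduces ``K``.
    Candidates are materialized lazily in blocks, in descending raw-value
    order, until the accumulated (rescaled) sum reaches ``alpha * trace(K)``;
    the materialized set is then re-sorted and truncated at the smallest p
    meeting the target, so ``alpha_achieved >= alpha`` always holds.

    Parameters
    ----------
    alpha
        Target fraction of ``trace(K)`` to capture, in (0, 1].  ``alpha=1``
        returns every candidate with positive value.
    rescale
        If False, keep the raw Kronecker eigenvalues ``d~_k`` (their sum then
        generally differs from ``trace(K)``); accumulation/truncation then
        uses the raw values.
    order_by
        ``"rescaled"`` (default) orders the basis by ``d*_k``; ``"raw"``
        keeps the raw Kronecker-product order ``d~_k``.
    block_size
        Number of candidate vectors materialized per block.

    Returns
    -------
    EVDResult
        Unit-norm columns; orthonormal only for balanced full-crossing
        designs, but always a spanning basis for the Hadamard kernel.
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if order_by not in ("rescaled", "raw"):
        raise ValueError(f"order_by must be 'rescaled' or 'raw', got {order_by!r}")
    ID1, ID2 = _check_ids(ID1, ID2)
    i1 = K1.positions(ID1)
    i2 = K2.positions(ID2)
    n = len(i1)

    e1 = eigen_sym(K1, clamp_tol)
    e2 = eigen_sym(K2, clamp_tol)
    # trace(K) without forming K
    trace_K = float(np.sum(K1.values[i1, i1] * K2.values[i2, i2]))

    V1o = e1.vectors[i1, :]  # n x n1, observation-indexed (Z1 V1)
    V2o = e2.vectors[i2, :]
    ii, jj, raw = _candidate_order(e1.values, e2.values)

    target = alpha * trace_K
    kept_U: list[np.ndarray] = []
    kept_val: list[np.ndarray] = []
    kept_src: list[np.ndarray] = []
    acc = 0.0
    n_zero_norm = 0
    N = len(raw)
    for start in range(0, N, block_size):
        stop = min(start + block_size, N)
        pos = raw[start:stop] > 0.0
        if not pos.any():
            break  # raw values descend; nothing positive remains
        bi, bj, braw = ii[start:stop][pos], jj[start:stop][pos], raw[start:stop][pos]
        W = V1o[:, bi] * V2o[:, bj]
        nrm2 = np.einsum("ij,ij->j", W, W)
        nz = nrm2 > 0.0
        n_zero_norm += int((~nz).sum())
        if nz.any():
            U = W[:, nz] / np.sqrt(nrm2[nz])
            dstar = braw[nz] * nrm2[nz] if rescale else braw[nz]
            kept_U.append(U)
            kept_val.append(dstar)
            kept_src.append(np.column_stack([bi[nz], bj[nz]]))
            acc += float(dstar.sum())
        if alpha < 1.0 and acc >= target:
            break

    if n_zero_norm:
        logger.debug("dropped %d zero-norm candidate vectors", n_zero_norm)

    if not kept_U:
        return EVDResult(
            vectors=np.zeros((n, 0)),
            values=np.zeros(0),
            total_variance=trace_K,
            alpha_requested=alpha,
            alpha_achieved=1.0 if trace_K == 0 else 0.0,
        )

    U = np.concatenate(kept_U, axis=1)
    vals = np.concatenate(kept_val)
    src = np.concatenate(kept_src, axis=0)

    if order_by == "rescaled":
        # stable: preserves the raw-order (i asc, j asc) tie-break
        perm = np.argsort(-vals, kind="stable")
        U, vals, src = U[:, perm], vals[perm], src[perm]

    if alpha < 1.0:
        csum = np.cumsum(vals)
        p = int(np.searchsorted(csum, target - 1e-12 * max(1.0, abs(target)))) + 1
        p = min(p, len(vals))
        U, vals, src = U[:, :p], vals[:p], src[:p]

    achieved = float(vals.sum() / trace_K) if trace_K > 0 else 1.0
    return EVDResult(
        vectors=U,
        values=vals,
        total_variance=trace_K,
        alpha_requested=alpha,
        alpha_achieved=achieved,
        source_indices=src,
    )


def reconstruct(evd: EVDResult) -> np.ndarray:
    """Return ``V diag(values) V'`` — the matrix implied by a basis."""
    if evd.n_vectors == 0:
        return np.zeros((evd.n, evd.n))
    Vd = evd.vectors * evd.values
    M = Vd @ evd.vectors.T
    return 0.5 * (M + M.T)


def truncate_evd(evd: EVDResult, alpha: float) -> EVDResult:
    """Truncate a (descending) eigen basis at the smallest p capturing alpha of the trace."""
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if alpha == 1.0:
        keep = evd.values > 0.0
        p = int(keep.sum())
    else:
        csum = np.cumsum(evd.values)
        target = alpha * evd.total_variance
        p = int(np.searchsorted(csum, target - 1e-12 * max(1.0, abs(target)))) + 1
        p = min(p, len(evd.values))
    src = evd.source_indices[:p] if len(evd.source_indices) else evd.source_indices
    total = evd.total_variance
    return EVDResult(
        vectors=evd.vectors[:, :p],
        values=evd.values[:p],
        total_variance=total,
        alpha_requested=alpha,
        alpha_achieved=float(evd.values[:p].sum() / total) if total > 0 else 1.0,
        source_indices=src,
    )
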