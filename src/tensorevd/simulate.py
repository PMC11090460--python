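"""Seeded generators for kernels, unbalanced designs, and phenotypes.

These emulate a multi-environment plant-breeding trial: a marker-derived
genomic relationship matrix (GRM) over genotypes, a covariate-derived
environmental relationship matrix (ERM) over environments, an unbalanced
replicated design sampling genotype-environment cells up to a target sample
size, and phenotypes drawn from the Gaussian reaction-norm model

    y = mu + G + E + GE + eps,
    G ~ MVN(0, var_g * K_G),  E ~ MVN(0, var_e * K_E),
    GE ~ MVN(0, var_ge * K),  eps ~ iid N(0, var_err),

with K the Hadamard-product interaction kernel of the design.  All
generators are pure functions of their seeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import DesignError, Kernel, eigen_sym, tensor_evd

__all__ = [
    "Design",
    "simulate_grm",
    "simulate_erm",
    "sample_design",
    "simulate_phenotypes",
]


@dataclass
class Design:
    """An unbalanced replicated layout: per-observation genotype and environment IDs."""

    id1: np.ndarray  # genotype label per observation
    id2: np.ndarray  # environment label per observation
    n_g: int
    n_e: int
    n: int
    seed: int


def simulate_grm(
    n_g: int,
    n_markers: int = 1000,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
) -> Kernel:
    """Marker-derived genomic relationship matrix (centered cross-product form).

    Draws biallelic genotype dosages (0/1/2) with per-marker allele
    frequencies uniform in ``maf_range``, centers by twice the realized
    allele frequency, and scales by ``sum(2 p (1 - p))`` so the diagonal
    averages near 1 — the standard GRM construction for unrelated founders.
    """
    lo, hi = maf_range
    if not (0.0 < lo < hi <= 0.5):
        raise ValueError(f"maf_range must satisfy 0 < lo < hi <= 0.5, got {maf_range}")
    if n_g < 2:
        raise ValueError("need at least 2 genotypes")
    if n_markers < 1:
        raise ValueError("need at least 1 marker")
    rng = np.random.default_rng(seed)
    p = rng.uniform(lo, hi, size=n_markers)
    X = rng.binomial(2, p, size=(n_g, n_markers)).astype(float)
    p_hat = X.mean(axis=0) / 2.0
    W = X - 2.0 * p_hat
    denom = float(np.sum(2.0 * p_hat * (1.0 - p_hat)))
    if denom <= 0.0:
        raise ValueError("all markers are monomorphic in the sample; increase n_markers")
    G = (W @ W.T) / denom
    labels = np.array([f"G{i + 1:04d}" for i in range(n_g)])
    return Kernel(values=G, labels=labels)


def simulate_erm(
    n_e: int,
    n_covariates: int = 20,
    bandwidth: float = 1.0,
    seed: int = 0,
) -> Kernel:
    """Environmental relationship matrix from a Gaussian kernel over covariates.

    Standard-normal covariates per environment; similarity
    ``exp(-||x_i - x_j||^2 / (2 * bandwidth^2 * n_covariates))``.  Unit
    diagonal, PSD.
    """
    if n_e < 2:
        raise ValueError("need at least 2 environments")
    if n_covariates < 1:
        raise ValueError("need at least 1 covariate")
    if bandwidth <= 0.0:
        raise ValueError(f"bandwidth must be positive, got {bandwidth}")
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_e, n_covariates))
    sq = np.sum(X**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.clip(d2, 0.0, None, out=d2)
    K = np.exp(-d2 / (2.0 * bandwidth**2 * n_covariates))
    np.fill_diagonal(K, 1.0)
    labels = np.array([f"E{j + 1:03d}" for j in range(n_e)])
    return Kernel(values=K, labels=labels)


def sample_design(
    kernel1_labels,
    kernel2_labels,
    n_g: int,
    n_e: int,
    n: int,
    seed: int = 0,
    force_balanced: bool = False,
) -> Design:
    """Sample an unbalanced replicated design.

    Picks ``n_g`` genotype labels and ``n_e`` environment labels without
    replacement, then assigns each of the ``n`` observations a cell of the
    ``n_g x n_e`` grid uniformly with replacement — after first guaranteeing
    that every sampled genotype and every sampled environment occurs at
    least once (feasible whenever ``n >= max(n_g, n_e)``).  With
    ``force_balanced=True`` the design is the exact full crossing
    (requires ``n == n_g * n_e``), one observation per cell.
    """
    kernel1_labels = np.asarray(kernel1_labels, dtype=str)
    kernel2_labels = np.asarray(kernel2_labels, dtype=str)
    if n_g > len(kernel1_labels) or n_e > len(kernel2_labels):
        raise DesignError(
            f"cannot sample {n_g} of {len(kernel1_labels)} genotypes / "
            f"{n_e} of {len(kernel2_labels)} environments"
        )
    if n_g < 1 or n_e < 1:
        raise DesignError("n_g and n_e must be at least 1")
    rng = np.random.default_rng(seed)
    g_labels = rng.choice(kernel1_labels, size=n_g, replace=False)
    e_labels = rng.choice(kernel2_labels, size=n_e, replace=False)

    if force_balanced:
        if n != n_g * n_e:
            raise DesignError(
                f"force_balanced requires n == n_g * n_e ({n_g * n_e}), got n={n}"
            )
        gi, ei = np.meshgrid(np.arange(n_g), np.arange(n_e), indexing="ij")
        gi, ei = gi.ravel(), ei.ravel()
    else:
        m = max(n_g, n_e)
        if n < m:
            raise DesignError(
                f"n={n} too small to cover {n_g} genotypes and {n_e} environments "
                f"(need at least {m})"
            )
        # coverage block: cycle both factors so each level appears at least once
        gi = np.arange(m) % n_g
        ei = np.arange(m) % n_e
        extra = n - m
        if extra > 0:
            gi = np.concatenate([gi, rng.integers(0, n_g, size=extra)])
            ei = np.concatenate([ei, rng.integers(0, n_e, size=extra)])
        perm = rng.permutation(n)
        gi, ei = gi[perm], ei[perm]

    return Design(
        id1=g_labels[gi],
        id2=e_labels[ei],
        n_g=n_g,
        n_e=n_e,
        n=n,
        seed=seed,
    )


def _mvn_from_eigen(evd, scale: float, rng: np.random.Generator) -> np.ndarray:
    """Draw MVN(0, scale * V diag(d) V') via the eigen factor (stable for singular kernels)."""
    z = rng.standard_normal(evd.n_vectors)
    return np.sqrt(scale) * (evd.vectors @ (np.sqrt(evd.values) * z))


def simulate_phenotypes(
    design: Design,
    K_G: Kernel,
    K_E: Kernel,
    var_g: float = 0.3,
    var_e: float = 0.3,
    var_ge: float = 0.2,
    var_err: float = 0.2,
    mu: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw phenotypes from the reaction-norm model on a given design.

    Genotype and environment main effects are MVN with the respective kernel;
    the interaction is MVN with the design's Hadamard kernel, drawn through
    its tensor-EVD factor so the n x n matrix is never formed.  Returns a
    table with columns ``id1``, ``id2``, ``y``.
    """
    for name, v in (("var_g", var_g), ("var_e", var_e), ("var_ge", var_ge), ("var_err", var_err)):
        if v < 0.0:
            raise ValueError(f"{name} must be nonnegative, got {v}")
    rng = np.random.default_rng(seed)
    i1 = K_G.positions(design.id1)
    i2 = K_E.positions(design.id2)
    n = len(i1)

    y = np.full(n, float(mu))
    if var_g > 0.0:
        G = _mvn_from_eigen(eigen_sym(K_G), var_g, rng)
        y += G[i1]
    if var_e > 0.0:
        E = _mvn_from_eigen(eigen_sym(K_E), var_e, rng)
        y += E[i2]
    if var_ge > 0.0:
        basis = tensor_evd(K_G, K_E, design.id1, design.id2, alpha=1.0)
        y += _mvn_from_eigen(basis, var_ge, rng)
    if var_err > 0.0:
        y += np.sqrt(var_err) * rng.standard_normal(n)

    return pd.DataFrame({"id1": design.id1, "id2": design.id2, "y": y})
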