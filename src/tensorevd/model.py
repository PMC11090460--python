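"""Eigen-basis Gaussian reaction-norm model: Gibbs sampling and CV1.

The mixed model

    y = mu + Z1 G + Z2 E + GE + eps

with G ~ MVN(0, sG2 K_G), E ~ MVN(0, sE2 K_E), GE ~ MVN(0, sGE2 K) and iid
Gaussian error is fitted in its equivalent eigen-basis form: each random
term u_t is represented as B_t theta_t with theta_t ~ N(0, s_t^2 D_t),
where (B_t, D_t) come from an :class:`~tensorevd.core.EVDResult` of the
term's observation-level kernel.  Whether that basis is exact (direct
eigendecomposition, alpha = 1) or a truncated tensor-EVD basis is decided by
the caller; the sampler only sees bases.

Sampling is a scalar Gibbs scheme: conjugate normal updates for the
intercept and each basis coefficient (updated in a fixed order against a
running residual), and scaled-inverse-chi-square updates for each variance
with degrees of freedom ``prior_df`` and prior scales allocating a fixed
partition of the sample phenotypic variance.  Deterministic given the seed.

Cross-validation follows the CV1 scheme: whole genotypes (all their
records) are assigned to folds, so test genotypes are entirely unseen
during training; predictions for them flow through the environment main
effect and through the genotype/interaction basis rows of the held-out
observations, which exist because the bases are observation-indexed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import EVDResult, Kernel, eigen_sym, hadamard_kernel, tensor_evd, truncate_evd


def _coefficient_sweep(Bt, bnorm2, prior_prec, inv_se, e, theta, z):
    """One Gibbs sweep of conjugate normal updates over all basis coefficients.

    Updates ``theta`` and the residual ``e`` in place, visiting coefficients
    in index order.  ``prior_prec[k] = 1 / (sigma_t^2 d_k)`` encodes the
    per-term variance, so one sweep covers all terms.
    """
    p = Bt.shape[0]
    for k in range(p):
        bk = Bt[k]
        old = theta[k]
        rhs = (np.dot(bk, e) + bnorm2[k] * old) * inv_se
        prec = bnorm2[k] * inv_se + prior_prec[k]
        new = rhs / prec + z[k] / np.sqrt(prec)
        if new != old:
            e += bk * (old - new)
            theta[k] = new


try:  # compiled sweep: ~100x faster for the large bases the method targets
    from numba import njit

    _coefficient_sweep = njit(cache=True)(_coefficient_sweep)
except ImportError:  # pragma: no cover - numba is an optional accelerator
    pass

__all__ = [
    "ReactionNormFit",
    "CVResult",
    "expand_basis",
    "build_ge_basis",
    "fit_reaction_norm",
    "variance_partition",
    "cv1_folds",
    "cv_evaluate",
]

TERMS = ("G", "E", "GE")


@dataclass
class ReactionNormFit:
    """Posterior draws and summaries of the reaction-norm model."""

    mu_samples: np.ndarray
    var_samples: dict[str, np.ndarray]  # keys: G, E, GE, error
    effect_posterior_means: dict[str, np.ndarray]  # per-term length-n fitted contributions
    theta_posterior_means: dict[str, np.ndarray]  # per-term basis coefficients
    mu_mean: float
    n_iter: int
    burn_in: int
    thin: int
    seed: int


@dataclass
class CVResult:
    """CV1 results: per-environment prediction correlations and their weighted mean."""

    fold_assignments: dict[str, int]
    env_correlations: pd.DataFrame  # columns: environment, r, n_obs
    weighted_mean_r: float
    skipped_environments: list[str] = field(default_factory=list)
    predictions: pd.DataFrame | None = None


def expand_basis(K: Kernel, ids, alpha: float = 1.0) -> EVDResult:
    """Observation-level eigen basis of ``Z K Z'`` for a main-effect term.

    Implemented as a tensor-EVD against a 1x1 unit kernel, which indexes the
    kernel's eigenvectors by the ID vector and renormalizes — exact at
    ``alpha = 1`` for any replicated design.
    """
    unit = Kernel(values=np.ones((1, 1)), labels=np.array(["_"]))
    ones = np.full(len(np.asarray(ids, dtype=str)), "_")
    return tensor_evd(K, unit, ids, ones, alpha=alpha)


def build_ge_basis(
    K_G: Kernel,
    K_E: Kernel,
    id1,
    id2,
    alpha: float = 0.95,
    method: str = "tensor",
) -> EVDResult:
    """Basis for the interaction kernel ``(Z1 K_G Z1') ∘ (Z2 K_E Z2')``.

    ``method="tensor"`` uses :func:`~tensorevd.core.tensor_evd` (never forms
    the n x n matrix); ``method="eigen"`` forms the Hadamard kernel
    explicitly, eigendecomposes it, and truncates at ``alpha`` — the exact
    but O(n^3) comparator.
    """
    if method == "tensor":
        return tensor_evd(K_G, K_E, id1, id2, alpha=alpha)
    if method == "eigen":
        K = hadamard_kernel(K_G, K_E, id1, id2)
        return truncate_evd(eigen_sym(K), alpha)
    raise ValueError(f"method must be 'tensor' or 'eigen', got {method!r}")


def _prepare_term(basis: EVDResult, n: int, name: str):
    if basis.n != n:
        raise ValueError(
            f"basis {name!r} has {basis.n} rows but the phenotype table has {n}"
        )
    keep = basis.values > 0.0
    Bt = np.ascontiguousarray(basis.vectors[:, keep].T)  # p x n, rows contiguous
    d = basis.values[keep].copy()
    return Bt, d


def fit_reaction_norm(
    y,
    basis_G: EVDResult,
    basis_E: EVDResult,
    basis_GE: EVDResult,
    n_iter: int = 1500,
    burn_in: int = 500,
    thin: int = 5,
    seed: int = 0,
    prior_df: float = 5.0,
    prior_var_partition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
) -> ReactionNormFit:
    """Gibbs sampler for the eigen-basis reaction-norm model.

    Parameters
    ----------
    y
        Length-n phenotype vector, or a table with a ``y`` column, aligned
        row-for-row with the bases.
    basis_G, basis_E, basis_GE
        Observation-level eigen bases (n rows each) for the genotype,
        environment, and interaction terms.
    prior_df, prior_var_partition
        Scaled-inverse-chi-square prior: degrees of freedom, and the
        fractions of the sample phenotypic variance allocated to
        (G, E, GE, error) as prior modes.
    """
    if isinstance(y, pd.DataFrame):
        y = y["y"].to_numpy()
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotypes contain non-finite values")
    n = len(y)
    if not (n_iter > burn_in >= 0):
        raise ValueError(f"need n_iter > burn_in >= 0, got {n_iter}, {burn_in}")
    if thin < 1:
        raise ValueError("thin must be >= 1")
    part = np.asarray(prior_var_partition, dtype=float)
    if part.shape != (4,) or np.any(part <= 0):
        raise ValueError("prior_var_partition must be 4 positive fractions (G, E, GE, error)")
    part = part / part.sum()

    bases = {"G": basis_G, "E": basis_E, "GE": basis_GE}
    Bt, d, term_slices = [], [], {}
    start = 0
    for t in TERMS:
        bt, dt = _prepare_term(bases[t], n, t)
        Bt.append(bt)
        d.append(dt)
        term_slices[t] = slice(start, start + len(dt))
        start += len(dt)
    Bt = np.concatenate(Bt, axis=0) if start else np.zeros((0, n))
    d = np.concatenate(d) if start else np.zeros(0)
    p_tot = len(d)
    # per-column squared norms: 1 for full bases, but subsetted rows (CV) differ
    bnorm2 = np.einsum("ij,ij->i", Bt, Bt)

    vary = float(np.var(y)) if n > 1 else 1.0
    if vary <= 0.0:
        vary = 1.0
    # prior scale: mode of scaled-inv-chi2(df, S) is df*S/(df+2); set mode = partition*var(y)
    S0 = {t: part[k] * vary * (prior_df + 2.0) / prior_df for k, t in enumerate(TERMS)}
    S0["error"] = part[3] * vary * (prior_df + 2.0) / prior_df

    rng = np.random.default_rng(seed)
    mu = float(np.mean(y))
    theta = np.zeros(p_tot)
    e = y - mu
    sig2 = {t: max(part[k] * vary, 1e-8) for k, t in enumerate(TERMS)}
    sig2_e = max(part[3] * vary, 1e-8)

    n_saved = (n_iter - burn_in + thin - 1) // thin
    mu_draws = np.empty(n_saved)
    var_draws = {t: np.empty(n_saved) for t in (*TERMS, "error")}
    effect_sums = {t: np.zeros(n) for t in TERMS}
    theta_sum = np.zeros(p_tot)
    saved = 0

    for it in range(n_iter):
        # intercept (flat prior)
        mu_new = float(np.mean(e)) + mu + np.sqrt(sig2_e / n) * rng.standard_normal()
        e += mu - mu_new
        mu = mu_new

        # scalar coefficient updates against the running residual
        z = rng.standard_normal(p_tot)
        prior_prec = np.empty(p_tot)
        for t in TERMS:
            sl = term_slices[t]
            prior_prec[sl] = 1.0 / (sig2[t] * d[sl])
        _coefficient_sweep(Bt, bnorm2, prior_prec, 1.0 / sig2_e, e, theta, z)

        # variance components: scaled-inverse-chi-square full conditionals
        for t in TERMS:
            sl = term_slices[t]
            p_t = sl.stop - sl.start
            ss = float(np.sum(theta[sl] ** 2 / d[sl]))
            sig2[t] = (ss + prior_df * S0[t]) / rng.chisquare(prior_df + p_t)
        ss_e = float(e @ e)
        sig2_e = (ss_e + prior_df * S0["error"]) / rng.chisquare(prior_df + n)

        if it >= burn_in and (it - burn_in) % thin == 0:
            mu_draws[saved] = mu
            for t in TERMS:
                var_draws[t][saved] = sig2[t]
            var_draws["error"][saved] = sig2_e
            for t in TERMS:
                sl = term_slices[t]
                effect_sums[t] += theta[sl] @ Bt[sl]
            theta_sum += theta
            saved += 1

    effects = {t: effect_sums[t] / max(saved, 1) for t in TERMS}
    theta_mean = theta_sum / max(saved, 1)
    return ReactionNormFit(
        mu_samples=mu_draws[:saved],
        var_samples={t: var_draws[t][:saved] for t in (*TERMS, "error")},
        effect_posterior_means=effects,
        theta_posterior_means={t: theta_mean[term_slices[t]] for t in TERMS},
        mu_mean=float(np.mean(mu_draws[:saved])),
        n_iter=n_iter,
        burn_in=burn_in,
        thin=thin,
        seed=seed,
    )


def variance_partition(fit: ReactionNormFit) -> dict[str, float]:
    """Posterior-mean variance of each term divided by their sum (sums to 1)."""
    means = {t: float(np.mean(v)) for t, v in fit.var_samples.items()}
    total = sum(means.values())
    return {t: m / total for t, m in means.items()}


def cv1_folds(hybrid_labels, k: int = 10, seed: int = 0) -> dict[str, int]:
    """Partition genotypes (not observations) into k nearly equal folds."""
    labels = np.asarray(hybrid_labels, dtype=str)
    uniq = np.unique(labels)
    if not (2 <= k <= len(uniq)):
        raise ValueError(f"k must be in [2, {len(uniq)}], got {k}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(uniq)
    folds = {}
    for f, chunk in enumerate(np.array_split(perm, k)):
        for lab in chunk:
            folds[str(lab)] = f
    return folds


def _subset_basis(basis: EVDResult, rows: np.ndarray) -> EVDResult:
    return EVDResult(
        vectors=basis.vectors[rows],
        values=basis.values,
        total_variance=basis.total_variance,
        alpha_requested=basis.alpha_requested,
        alpha_achieved=basis.alpha_achieved,
        source_indices=basis.source_indices,
    )


def cv_evaluate(
    y_table: pd.DataFrame,
    basis_G: EVDResult,
    basis_E: EVDResult,
    basis_GE: EVDResult,
    folds: dict[str, int],
    min_env_obs: int = 3,
    **fit_kwargs,
) -> CVResult:
    """CV1 cross-validation of the reaction-norm model.

    For each fold, refits on the training observations (bases subset by
    row) and predicts held-out observations as
    ``mu + B_G theta_G + B_E theta_E + B_GE theta_GE`` using posterior
    means.  Reports the within-environment Pearson correlation of predicted
    vs observed over all held-out records, and the n-weighted mean across
    environments; environments with fewer than ``min_env_obs`` held-out
    records are skipped and flagged.
    """
    y = y_table["y"].to_numpy(dtype=float)
    id1 = y_table["id1"].to_numpy(dtype=str)
    id2 = y_table["id2"].to_numpy(dtype=str)
    n = len(y)
    fold_of_obs = np.array([folds[g] for g in id1])
    n_folds = int(fold_of_obs.max()) + 1
    yhat = np.full(n, np.nan)
    seed0 = int(fit_kwargs.pop("seed", 0))

    for f in range(n_folds):
        test = fold_of_obs == f
        train = ~test
        if not test.any():
            raise ValueError(f"fold {f} has no test observations")
        fit = fit_reaction_norm(
            y[train],
            _subset_basis(basis_G, train),
            _subset_basis(basis_E, train),
            _subset_basis(basis_GE, train),
            seed=seed0 + f,
            **fit_kwargs,
        )
        pred = np.full(int(test.sum()), fit.mu_mean)
        # posterior-mean coefficients applied to the held-out basis rows
        for t, basis in (("G", basis_G), ("E", basis_E), ("GE", basis_GE)):
            pred += basis.vectors[test][:, basis.values > 0.0] @ fit.theta_posterior_means[t]
        yhat[test] = pred

    rows, skipped = [], []
    for env in np.unique(id2):
        m = id2 == env
        if m.sum() < min_env_obs:
            skipped.append(str(env))
            continue
        obs, pred = y[m], yhat[m]
        if np.std(obs) == 0.0 or np.std(pred) == 0.0:
            skipped.append(str(env))
            continue
        r = float(np.corrcoef(obs, pred)[0, 1])
        rows.append({"environment": str(env), "r": r, "n_obs": int(m.sum())})
    env_df = pd.DataFrame(rows, columns=["environment", "r", "n_obs"])
    if len(env_df):
        w = env_df["n_obs"].to_numpy(dtype=float)
        wmean = float(np.sum(env_df["r"].to_numpy() * w) / w.sum())
    else:
        wmean = float("nan")
    preds = y_table.copy()
    preds["y_pred"] = yhat
    return CVResult(
        fold_assignments=dict(folds),
        env_correlations=env_df,
        weighted_mean_r=wmean,
        skipped_environments=skipped,
        predictions=preds,
    )
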