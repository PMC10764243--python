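"""Negative-binomial mixture clustering of per-gene expression effects.

Each gene ``g`` is summarised by a sum-to-zero effect vector
``beta_g = (beta_g1, ..., beta_gI)``: the log deviation of each group's
normalized mean expression from the gene's overall log mean.  Genes are
clustered by fitting a ``K``-component mixture in which component ``k``
imposes a shared effect vector ``mu_k`` (also sum-to-zero) on every member
gene, while a per-gene baseline ``a_g`` and a per-gene dispersion ``phi_g``
absorb expression level and biological variability.

The component objective is the negative-binomial log-density evaluated at
the model-scale pseudo-counts ``x_gj = y_gj / factor_j`` (continuous
extension through the gamma function) with mean ``exp(a_g + mu_k,i(j))``
and variance ``mean + phi_g * mean**2``; equivalently, on the raw count
scale the mean is ``exp(a_g + mu_k,i(j) + log_factor_j)`` — the log
normalization factor enters the mean as an *added* offset, the convention
of the underlying model-based clustering machinery.  With CPM factors
(``1e6 / library_size``) this deliberately moves apparent expression *with*
the realized library imbalance rather than against it, which is what keeps
the minimum-norm rule pointed at the non-DEG cluster even when most DEGs
are up-regulated in one group and the library sizes are skewed.  The fit
depends on counts and factors only through ``y_gj / factor_j``, so jointly
multiplying one sample's counts and its factor by the same constant leaves
every estimate unchanged.  The objective is concave in ``(a_g, mu)``; the
EM loop below maximises it by Newton steps with backtracking and is
monotone in the mixture log-likelihood.

Fitting proceeds in three stages mirroring the classic pipeline: data
preparation (:func:`estimate_gene_effects`, :func:`estimate_dispersions`),
k-means++ seeding of the centers (:func:`kmeanspp_init`), and EM
(:func:`em_fit`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

from .io_core import CountMatrix, GroupDesign
from .normalization import NormalizationFactors

__all__ = [
    "GeneEffects",
    "ClusterModel",
    "estimate_gene_effects",
    "kmeanspp_init",
    "nb_log_pmf",
    "estimate_dispersions",
    "em_fit",
    "DEFAULT_PSEUDO",
]

logger = logging.getLogger(__name__)

DEFAULT_PSEUDO = 0.25  # pseudo-count on the normalized scale for beta-hat logs
_DISPERSION_FLOOR = 1e-8  # NB computations stay numerically Poisson below this
_EMPTY_FRACTION = 1e-6  # component responsibility below this * G triggers rescue


@dataclass
class GeneEffects:
    """Initial per-gene baseline and sum-to-zero effect estimates.

    ``baseline[g]`` is the mean over groups of ``ln(m_gi + pseudo)`` where
    ``m_gi`` is the group mean of normalized counts; ``beta_hat[g]`` is the
    per-group deviation from that baseline (rows sum to zero).
    """

    baseline: np.ndarray
    beta_hat: np.ndarray


@dataclass
class ClusterModel:
    """A fitted K-component mixture over gene effect vectors."""

    K: int
    centers: np.ndarray  # (K, I), rows sum to zero
    weights: np.ndarray  # (K,) mixture proportions
    dispersions: np.ndarray  # (G,) per-gene NB dispersion, fixed during EM
    posteriors: np.ndarray  # (G, K), rows sum to one
    loglik_trace: np.ndarray
    n_iter: int
    converged: bool
    n_rescues: int = 0
    baseline: np.ndarray = field(default=None, repr=False)


def _model_scale(counts: CountMatrix, norm: NormalizationFactors) -> np.ndarray:
    """Counts on the model scale: ``y_gj / factor_j``.

    The mixture models raw counts with mean ``exp(a_g + mu_ki +
    log_factor_j)``; dividing by the factor moves the data onto the scale
    where the mean is ``exp(a_g + mu_ki)``.
    """
    return counts.counts / norm.factor


def _group_means(x: np.ndarray, design: GroupDesign) -> np.ndarray:
    """Mean of ``x`` (genes x samples) over the replicates of each group."""
    i = design.n_groups
    out = np.empty((x.shape[0], i))
    for g in range(i):
        out[:, g] = x[:, design.group_index == g].mean(axis=1)
    return out


def estimate_gene_effects(
    counts: CountMatrix,
    design: GroupDesign,
    norm: NormalizationFactors,
    pseudo: float = DEFAULT_PSEUDO,
) -> GeneEffects:
    """Initial per-gene effect vectors from normalized group means.

    ``beta_hat[g, i] = ln(m_gi + pseudo) - mean_i ln(m_gi + pseudo)`` with
    ``m_gi`` the group-``i`` mean of the model-scale counts
    ``count / factor``.  The pseudo-count keeps logs finite for groups with
    all-zero counts.
    """
    if pseudo <= 0:
        raise ValueError("pseudo must be positive")
    x = _model_scale(counts, norm)
    logm = np.log(_group_means(x, design) + pseudo)
    baseline = logm.mean(axis=1)
    return GeneEffects(baseline=baseline, beta_hat=logm - baseline[:, None])


def kmeanspp_init(effects: GeneEffects, K: int, seed: int) -> np.ndarray:
    """Seed ``K`` cluster centers from the beta-hat rows by k-means++.

    The first center is a uniformly random row; each subsequent center is a
    row drawn with probability proportional to its squared Euclidean
    distance to the nearest center chosen so far.  Centers are recentred to
    sum to zero.  Deterministic given ``seed``.
    """
    x = np.asarray(effects.beta_hat, dtype=float)
    g = x.shape[0]
    if K < 1 or K > g:
        raise ValueError(f"K={K} out of range for {g} genes")
    n_distinct = np.unique(x, axis=0).shape[0]
    if K > n_distinct:
        raise ValueError(f"K={K} exceeds the {n_distinct} distinct effect rows")
    rng = np.random.default_rng(seed)
    chosen = [int(rng.integers(g))]
    d2 = ((x - x[chosen[0]]) ** 2).sum(axis=1)
    for _ in range(1, K):
        total = d2.sum()
        p = d2 / total
        idx = int(rng.choice(g, p=p))
        chosen.append(idx)
        d2 = np.minimum(d2, ((x - x[idx]) ** 2).sum(axis=1))
    centers = x[chosen].copy()
    centers -= centers.mean(axis=1, keepdims=True)
    return centers


def nb_log_pmf(y, mean, dispersion):
    """Log-pmf of the negative binomial with mean/dispersion parameterization.

    ``E[Y] = mean`` and ``Var[Y] = mean + dispersion * mean**2``; at
    ``dispersion = 0`` this is the Poisson log-pmf.  Inputs broadcast;
    ``y`` may be non-integral (continuous extension through ``gammaln``).
    """
    y, mean, disp = np.broadcast_arrays(
        np.asarray(y, dtype=float),
        np.asarray(mean, dtype=float),
        np.asarray(dispersion, dtype=float),
    )
    if np.any(mean <= 0):
        raise ValueError("mean must be positive")
    if np.any(disp < 0):
        raise ValueError("dispersion must be nonnegative")
    out = np.empty(y.shape, dtype=float)
    pois = disp == 0
    if pois.any():
        out[pois] = y[pois] * np.log(mean[pois]) - mean[pois] - gammaln(y[pois] + 1)
    nb = ~pois
    if nb.any():
        r = 1.0 / disp[nb]
        s = disp[nb] * mean[nb]
        out[nb] = (
            gammaln(y[nb] + r)
            - gammaln(r)
            - gammaln(y[nb] + 1)
            + y[nb] * np.log(s)
            - (y[nb] + r) * np.log1p(s)
        )
    return out if out.ndim else float(out)


def estimate_dispersions(
    counts: CountMatrix, design: GroupDesign, norm: NormalizationFactors
) -> np.ndarray:
    """Per-gene NB dispersions by pooled method of moments, shrunk to the median.

    On model-scale counts, the raw estimate is
    ``max(0, (s2_pooled - mbar) / mbar**2)`` with ``s2_pooled`` the
    within-group variance pooled over groups and ``mbar`` the overall mean.
    Estimates are then shrunk halfway to the median raw estimate; genes with
    ``mbar = 0`` receive the median.  The dispersions are held fixed during
    EM.
    """
    n = counts.n_samples
    i = design.n_groups
    dof = n - i
    if dof < 1:
        raise ValueError(
            "dispersion is unidentifiable: every group has a single replicate"
        )
    x = _model_scale(counts, norm)
    centered = x - _group_means(x, design)[:, design.group_index]
    s2 = (centered**2).sum(axis=1) / dof
    mbar = x.mean(axis=1)
    expressed = mbar > 0
    if not expressed.any():
        raise ValueError("all genes have zero counts")
    raw = np.zeros(x.shape[0])
    raw[expressed] = np.maximum(
        0.0, (s2[expressed] - mbar[expressed]) / mbar[expressed] ** 2
    )
    med = float(np.median(raw[expressed]))
    phi = 0.5 * raw + 0.5 * med
    phi[~expressed] = med
    return phi


def _sum_zero_basis(i: int) -> np.ndarray:
    """Basis of the sum-to-zero subspace of R^I, shape (I, I-1)."""
    return np.vstack([np.eye(i - 1), -np.ones((1, i - 1))]) if i > 1 else np.zeros((1, 0))


def _component_q(x, xr, phi_col, w, a, mu_k, gi):
    """Weighted mu-dependent objective for one component (scalar)."""
    eta = a[:, None] + mu_k[gi][None, :]
    val = x * eta - xr * np.log1p(phi_col * np.exp(eta))
    return float(w @ val.sum(axis=1))


def _update_centers(x, xr, phi, a, mu, post, gi, basis, max_inner=3):
    """Constrained Newton ascent on each center's sum-to-zero coordinates."""
    if basis.shape[1] == 0:
        return mu
    i = mu.shape[1]
    phi_col = phi[:, None]
    new = mu.copy()
    for k in range(mu.shape[0]):
        w = post[:, k]
        mu_k = new[k].copy()
        for _ in range(max_inner):
            eta = a[:, None] + mu_k[gi][None, :]
            s = phi_col * np.exp(eta)
            u = s / (1.0 + s)
            score = w @ (x - xr * u)  # (N,) d/d eta
            curv = w @ (xr * u * (1.0 - u))
            grad = np.bincount(gi, weights=score, minlength=i)
            hess = np.bincount(gi, weights=curv, minlength=i)
            g_th = basis.T @ grad
            h_th = (basis.T * hess) @ basis
            try:
                step = np.linalg.solve(h_th, g_th)
            except np.linalg.LinAlgError:
                break
            dmu = basis @ step
            q0 = _component_q(x, xr, phi_col, w, a, mu_k, gi)
            t = 1.0
            for _ in range(12):
                if _component_q(x, xr, phi_col, w, a, mu_k + t * dmu, gi) >= q0:
                    break
                t *= 0.5
            else:
                t = 0.0
            mu_k = mu_k + t * dmu
            if np.abs(t * dmu).max() < 1e-9:
                break
        new[k] = mu_k
    return new


def _baseline_q(x, xr, phi3, post, a, mu_gi):
    """Per-gene a-dependent objective, shape (G,)."""
    eta = a[:, None, None] + mu_gi[None, :, :]
    val = x[:, None, :] * eta - xr[:, None, :] * np.log1p(phi3 * np.exp(eta))
    return (post * val.sum(axis=2)).sum(axis=1)


def _update_baseline(x, xr, phi, a, mu, post, gi, max_inner=2):
    """Vectorized per-gene Newton ascent on the baseline, with backtracking."""
    mu_gi = mu[:, gi]
    phi3 = phi[:, None, None]
    a = a.copy()
    for _ in range(max_inner):
        eta = a[:, None, None] + mu_gi[None, :, :]
        s = phi3 * np.exp(eta)
        u = s / (1.0 + s)
        score = x[:, None, :] - xr[:, None, :] * u
        grad = (post * score.sum(axis=2)).sum(axis=1)
        curv = (post * (xr[:, None, :] * u * (1.0 - u)).sum(axis=2)).sum(axis=1)
        da = grad / np.maximum(curv, 1e-12)
        q0 = _baseline_q(x, xr, phi3, post, a, mu_gi)
        bad = np.zeros(a.shape, dtype=bool)
        for _ in range(10):
            q1 = _baseline_q(x, xr, phi3, post, a + da, mu_gi)
            bad = q1 < q0
            if not bad.any():
                break
            da[bad] *= 0.5
        if bad.any():
            da[bad] = 0.0
        a = a + da
        if np.abs(da).max() < 1e-9:
            break
    return a


def em_fit(
    counts: CountMatrix,
    design: GroupDesign,
    norm: NormalizationFactors,
    K: int,
    init_centers: np.ndarray,
    dispersions: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 1000,
    pseudo: float = DEFAULT_PSEUDO,
) -> ClusterModel:
    """Fit the K-component NB mixture by EM.

    E-step: posterior ``p_gk`` proportional to ``pi_k *`` the component
    objective.  M-step: mixture weights from mean responsibilities; centers
    by Newton ascent in the sum-to-zero subspace; baselines re-profiled per
    gene.  Iterates until the relative change of the mixture log-likelihood
    falls below ``tol`` or ``max_iter`` is reached.

    A component whose total responsibility drops below ``1e-6 * G`` is
    re-seeded at the effect vector of the gene with the lowest maximum
    posterior (counted in ``n_rescues``; a rescue may transiently lower the
    trace).  Genes with zero total count are excluded from the fit and
    re-attached with posterior 1 in the minimum-norm (non-DEG) cluster.
    """
    init_centers = np.asarray(init_centers, dtype=float)
    i_groups = design.n_groups
    if init_centers.shape != (K, i_groups):
        raise ValueError("init_centers must have shape (K, I)")
    if np.abs(init_centers.sum(axis=1)).max() > 1e-8:
        raise ValueError("init_centers rows must sum to zero")
    if K < 1:
        raise ValueError("K must be at least 1")

    dispersions = np.asarray(dispersions, dtype=float)
    x_all = _model_scale(counts, norm)
    keep = x_all.sum(axis=1) > 0
    x = x_all[keep]
    g_fit = x.shape[0]
    if g_fit == 0:
        raise ValueError("no genes with nonzero counts")

    phi = np.maximum(dispersions[keep], _DISPERSION_FLOOR)
    r = 1.0 / phi
    xr = x + r[:, None]
    # observation constants of the NB objective (parameters enter elsewhere)
    const = (
        gammaln(x + r[:, None])
        - gammaln(r)[:, None]
        - gammaln(x + 1.0)
        + x * np.log(phi)[:, None]
    ).sum(axis=1)

    effects = estimate_gene_effects(counts, design, norm, pseudo=pseudo)
    beta_f = effects.beta_hat[keep]
    a = effects.baseline[keep].copy()
    mu = init_centers - init_centers.mean(axis=1, keepdims=True)
    pi = np.full(K, 1.0 / K)
    gi = design.group_index
    basis = _sum_zero_basis(i_groups)
    phi3 = phi[:, None, None]

    def component_loglik():
        eta = a[:, None, None] + mu[:, gi][None, :, :]
        val = x[:, None, :] * eta - xr[:, None, :] * np.log1p(phi3 * np.exp(eta))
        return const[:, None] + val.sum(axis=2)

    trace = []
    prev = None
    converged = False
    n_rescues = 0
    post = np.full((g_fit, K), 1.0 / K)
    it = 0
    for it in range(1, max_iter + 1):
        ll_gk = component_loglik()
        logw = np.log(pi)[None, :] + ll_gk
        norm_g = logsumexp(logw, axis=1)
        ll = float(norm_g.sum())
        if not np.isfinite(ll):
            raise FloatingPointError("non-finite mixture log-likelihood")
        post = np.exp(logw - norm_g[:, None])
        trace.append(ll)

        resp = post.sum(axis=0)
        weak = np.where(resp < _EMPTY_FRACTION * g_fit)[0]
        if weak.size:
            worst = int(np.argmin(post.max(axis=1)))
            for k in weak:
                mu[k] = beta_f[worst] - beta_f[worst].mean()
                pi[k] = 1.0 / g_fit
                n_rescues += 1
                logger.warning("re-seeded empty component %d at gene %d", k, worst)
            pi = pi / pi.sum()
            prev = None
            continue

        if prev is not None and abs(ll - prev) <= tol * (abs(prev) + 1e-300):
            converged = True
            break
        prev = ll

        pi = np.maximum(post.mean(axis=0), 1e-300)
        pi = pi / pi.sum()
        mu = _update_centers(x, xr, phi, a, mu, post, gi, basis)
        a = _update_baseline(x, xr, phi, a, mu, post, gi)

    posteriors = np.zeros((counts.n_genes, K))
    posteriors[keep] = post
    baseline_full = np.zeros(counts.n_genes)
    baseline_full[keep] = a
    if (~keep).any():
        k0 = int(np.argmin(np.linalg.norm(mu, axis=1)))
        posteriors[~keep, k0] = 1.0

    return ClusterModel(
        K=K,
        centers=mu,
        weights=pi,
        dispersions=dispersions,
        posteriors=posteriors,
        loglik_trace=np.asarray(trace),
        n_iter=it,
        converged=converged,
        n_rescues=n_rescues,
        baseline=baseline_full,
    )
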