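"""Genomic prediction models used to validate optimized training sets.

GBLUP fits y = 1*mu + g + e with g ~ N(0, sigma_g^2 A); the variance
components are estimated by restricted maximum likelihood through a spectral
decomposition of the (ridged) kinship, which is exact for a single random
effect. RKHS is the same machinery with a Gaussian kernel in place of A, so
substituting K = A reproduces GBLUP bit-for-bit. BayesB is a spike-and-slab
marker-effect model sampled by Gibbs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.spatial.distance import pdist, squareform

from .core import DEFAULT_RIDGE, MarkerMatrix, RelationshipMatrix


@dataclass
class GSModelFit:
    model_name: str
    genetic_variance: float
    residual_variance: float
    intercept: float
    gebv: dict[str, float]
    kernel: np.ndarray | None = None
    bandwidth: float | None = None
    extras: dict = field(default_factory=dict)

    def gebv_for(self, ids) -> np.ndarray:
        return np.array([self.gebv[s] for s in ids])


def _reml_spectral(y: np.ndarray, k_tt: np.ndarray):
    """REML for y = 1*mu + g + e, g ~ N(0, sg^2 K) via eigendecomposition.

    Profiles the restricted likelihood over the variance ratio
    delta = se^2 / sg^2 on a log grid refined by bounded scalar minimization.
    Returns (sg2, se2, mu, eigvals, eigvecs).
    """
    n = y.size
    evals, evecs = np.linalg.eigh(k_tt)
    if evals.min() < -1e-8:
        raise np.linalg.LinAlgError("kernel training block is not positive semi-definite")
    evals = np.clip(evals, 0.0, None)
    y_r = evecs.T @ y
    x_r = evecs.T @ np.ones((n, 1))

    def neg_restricted_ll(log_delta: float) -> float:
        delta = np.exp(log_delta)
        w = evals + delta
        xtvx = float((x_r[:, 0] ** 2 / w).sum())
        beta = float((x_r[:, 0] * y_r / w).sum()) / xtvx
        r = y_r - x_r[:, 0] * beta
        rss = float((r**2 / w).sum())
        sg2 = rss / (n - 1)
        if sg2 <= 0 or not np.isfinite(sg2):
            return np.inf
        return (n - 1) * np.log(sg2) + np.log(w).sum() + np.log(xtvx)

    grid = np.linspace(np.log(1e-6), np.log(1e6), 40)
    values = np.array([neg_restricted_ll(g) for g in grid])
    if not np.isfinite(values).any():
        raise RuntimeError("REML failed: restricted likelihood not finite on the grid")
    i = int(np.argmin(values))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    res = optimize.minimize_scalar(neg_restricted_ll, bounds=(lo, hi), method="bounded")
    if not res.success:  # pragma: no cover - bounded Brent rarely fails
        raise RuntimeError(f"REML non-convergence: {res}")
    delta = float(np.exp(res.x))
    w = evals + delta
    xtvx = float((x_r[:, 0] ** 2 / w).sum())
    mu = float((x_r[:, 0] * y_r / w).sum()) / xtvx
    r = y_r - x_r[:, 0] * mu
    sg2 = float((r**2 / w).sum()) / (n - 1)
    se2 = delta * sg2
    return sg2, se2, mu, evals, evecs, delta


def _fit_kernel_model(
    model_name: str,
    y_train: np.ndarray,
    kernel: np.ndarray,
    kernel_ids: list[str],
    training_ids,
    predict_ids,
    ridge: float,
    bandwidth: float | None = None,
) -> GSModelFit:
    lookup = {s: i for i, s in enumerate(kernel_ids)}
    t = np.array([lookup[s] for s in training_ids], dtype=int)
    p = np.array([lookup[s] for s in predict_ids], dtype=int)
    y = np.asarray(y_train, dtype=float)
    if y.size != t.size:
        raise ValueError("one phenotype per training individual required")
    k_tt = kernel[np.ix_(t, t)] + ridge * np.eye(t.size)
    sg2, se2, mu, evals, evecs, delta = _reml_spectral(y, k_tt)
    # BLUP: g_hat = K[p, t] (K_tt + delta I)^-1 (y - mu)
    resid_rot = evecs.T @ (y - mu)
    solve_rot = resid_rot / (evals + delta)
    weights = evecs @ solve_rot
    g_hat = kernel[np.ix_(p, t)] @ weights
    return GSModelFit(
        model_name=model_name,
        genetic_variance=sg2,
        residual_variance=se2,
        intercept=mu,
        gebv={s: float(v) for s, v in zip(predict_ids, g_hat)},
        kernel=kernel if model_name == "rkhs" else None,
        bandwidth=bandwidth,
        extras={"delta": delta},
    )


def fit_predict_gblup(
    y_train,
    A: RelationshipMatrix,
    training_ids,
    predict_ids,
    ridge: float = DEFAULT_RIDGE,
) -> GSModelFit:
    """GBLUP: additive kinship mixed model, REML variances, BLUP predictions."""
    return _fit_kernel_model(
        "gblup", np.asarray(y_train, float), A.values, list(A.ids), list(training_ids), list(predict_ids), ridge
    )


def gaussian_kernel(markers: MarkerMatrix, bandwidth: float | None = None):
    """K_ij = exp(-d_ij^2 / h) on column-standardized dosages.

    The default bandwidth h is the median off-diagonal squared distance; the
    kernel is symmetric positive semi-definite by construction.
    """
    x = markers.centered()
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    x = x / sd
    d2 = squareform(pdist(x, metric="sqeuclidean"))
    if bandwidth is None:
        off = d2[np.triu_indices_from(d2, k=1)]
        bandwidth = float(np.median(off))
        if bandwidth <= 0:
            raise ValueError("degenerate panel: zero median pairwise distance")
    return np.exp(-d2 / bandwidth), bandwidth


def fit_predict_rkhs(
    y_train,
    markers: MarkerMatrix,
    training_ids,
    predict_ids,
    bandwidth: float | None = None,
    ridge: float = DEFAULT_RIDGE,
) -> GSModelFit:
    """RKHS regression: the GBLUP machinery with a Gaussian kernel matrix."""
    kernel, h = gaussian_kernel(markers, bandwidth)
    return _fit_kernel_model(
        "rkhs", np.asarray(y_train, float), kernel, list(markers.sample_ids),
        list(training_ids), list(predict_ids), ridge, bandwidth=h,
    )


@dataclass
class BayesBConfig:
    """Spike-and-slab sampler settings (Meuwissen-lineage defaults).

    ``pi_nonzero`` is the prior inclusion probability of a marker; per-locus
    effect variances follow a scaled-inverse-chi-square with ``df`` degrees of
    freedom whose scale is matched to the phenotypic variance so the prior
    genetic variance is plausible a priori.
    """

    n_iter: int = 6000
    burn_in: int = 1000
    pi_nonzero: float = 0.05
    df: float = 5.0
    rng_seed: int = 0


def fit_predict_bayesb(
    y_train,
    markers: MarkerMatrix,
    training_ids,
    predict_ids,
    config: BayesBConfig | None = None,
) -> GSModelFit:
    """BayesB: marker effects are zero with probability 1 - pi, otherwise
    normal with a per-locus scaled-inverse-chi-square variance (a scaled-t
    marginal). Gibbs sampling; GEBVs are posterior-mean effects times the
    centered dosages."""
    config = config or BayesBConfig()
    if config.n_iter < 1000:
        raise ValueError("chain length must be at least 1000")
    rng = np.random.default_rng(config.rng_seed)
    y = np.asarray(y_train, dtype=float)
    t_idx = markers.index_of(training_ids)
    p_idx = markers.index_of(predict_ids)
    xc_all = markers.centered()
    x = xc_all[t_idx]
    n, m = x.shape
    xtx = (x**2).sum(axis=0)
    xtx = np.where(xtx <= 0, 1e-12, xtx)

    vy = y.var()
    pi = config.pi_nonzero
    df = config.df
    # prior scale: expected per-included-marker variance explains half of vy
    mean_x2 = float(xtx.mean() / n)
    scale = (vy * 0.5) / max(pi * m * mean_x2, 1e-12) * (df - 2) / df

    mu = float(y.mean())
    beta = np.zeros(m)
    delta_in = np.zeros(m, dtype=bool)
    sigma_j = np.full(m, scale * df / (df - 2))
    se2 = vy * 0.5
    resid = y - mu
    beta_sum = np.zeros(m)
    include_count = np.zeros(m)
    kept = 0

    for it in range(config.n_iter):
        # intercept
        resid += mu
        mu = float(resid.mean() + rng.normal(0.0, np.sqrt(se2 / n)))
        resid -= mu
        for j in range(m):
            xj = x[:, j]
            if delta_in[j]:
                resid += xj * beta[j]
            z = float(xj @ resid)
            v1 = xtx[j] ** 2 * sigma_j[j] + xtx[j] * se2
            v0 = xtx[j] * se2
            log_odds = (
                np.log(pi / (1.0 - pi))
                + 0.5 * (np.log(v0) - np.log(v1))
                + 0.5 * z**2 * (1.0 / v0 - 1.0 / v1)
            )
            p_in = 1.0 / (1.0 + np.exp(-np.clip(log_odds, -700, 700)))
            if rng.random() < p_in:
                c = xtx[j] + se2 / sigma_j[j]
                b = rng.normal(z / c, np.sqrt(se2 / c))
                beta[j] = b
                delta_in[j] = True
                resid -= xj * b
            else:
                beta[j] = 0.0
                delta_in[j] = False
            # per-locus variance update (scaled-inverse-chi-square conjugacy)
            ssq = beta[j] ** 2 if delta_in[j] else 0.0
            nu = df + (1.0 if delta_in[j] else 0.0)
            sigma_j[j] = (df * scale + ssq) / rng.chisquare(nu)
        se2 = float((resid @ resid + df * vy * 0.5) / rng.chisquare(n + df))
        if not np.isfinite(se2) or se2 <= 0:
            raise RuntimeError("divergent chain: residual variance not finite")
        if it >= config.burn_in:
            beta_sum += beta
            include_count += delta_in
            kept += 1

    beta_mean = beta_sum / kept
    g_all = xc_all @ beta_mean
    g_var = float(np.var(g_all[t_idx]))
    return GSModelFit(
        model_name="bayesb",
        genetic_variance=g_var,
        residual_variance=se2,
        intercept=mu,
        gebv={s: float(g_all[i]) for s, i in zip(predict_ids, p_idx)},
        extras={
            "posterior_inclusion": include_count / kept,
            "beta_mean": beta_mean,
        },
    )


def prediction_accuracy(gebv_predict, genotypic_values_predict) -> float:
    """Pearson correlation between GEBVs and the genotypic values."""
    a = np.asarray(gebv_predict, dtype=float)
    b = np.asarray(genotypic_values_predict, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("need at least three paired values")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(stats.pearsonr(a, b)[0])
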