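"""Training-set size optimization from a fitted evaluation-metric curve.

The evaluation metric (CDmean, Rscore, or an avg_grm variant computed on the
training sets produced at each tested size) is fitted against the training
set size s (% of the candidate set) with

    metric(s) = ln(s - d) / (m (s - d)^p) + n

whose shape parameter p classifies the curve: slowing growth (p < 0.5), a
plateau (0.5 < p < 1), or rapid growth followed by a slow decline (p > 1) —
the only regime with an interior maximum, at s* = d + e^(1/p). For monotone
regimes a size is chosen instead as the smallest s whose fitted metric
reaches a target fraction (e.g. 95% or 99%) of the fitted value at s = 100.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares


@dataclass
class SizeCurveFit:
    """Fitted parameters of the size curve and its regime classification."""

    d: float
    m: float
    p: float
    n: float
    rss: float
    regime: str  # slowing_growth | plateau | maximum
    min_size: float
    max_size: float

    def __call__(self, size) -> np.ndarray:
        size = np.asarray(size, dtype=float)
        u = size - self.d
        if np.any(u <= 0):
            raise ValueError("curve undefined at sizes <= d")
        return np.log(u) / (self.m * u**self.p) + self.n


def _classify(p: float) -> str:
    # boundary values map to the lower regime
    if p <= 0.5:
        if p in (0.5,):
            warnings.warn("p = 0.5 is a regime boundary; classified as slowing_growth")
        return "slowing_growth"
    if p <= 1.0:
        if p == 1.0:
            warnings.warn("p = 1 is a regime boundary; classified as plateau")
        return "plateau"
    return "maximum"


def _curve(params: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    d, m, p, n = params
    u = sizes - d
    return np.log(u) / (m * u**p) + n


def fit_size_curve(sizes, metric_values) -> SizeCurveFit:
    """Nonlinear least squares with multi-start initialization.

    Starts on a grid over d and p with m, n solved linearly at each start
    (the model is linear in 1/m and n once d and p are fixed), refined by
    bounded Levenberg-Marquardt; the best residual wins. Deterministic.
    """
    sizes = np.asarray(sizes, dtype=float)
    values = np.asarray(metric_values, dtype=float)
    if sizes.size != values.size:
        raise ValueError("sizes and metric values must align")
    if np.unique(sizes).size < 4:
        raise ValueError("need at least 4 distinct sizes for 4 free parameters")
    order = np.argsort(sizes)
    sizes, values = sizes[order], values[order]
    s_min = sizes.min()

    best = None
    d_grid = [0.0, 0.5 * s_min, 0.9 * s_min]
    p_grid = [0.3, 0.7, 1.5]
    for d0 in d_grid:
        u = sizes - d0
        if np.any(u <= 0):
            continue
        for p0 in p_grid:
            basis = np.log(u) / u**p0
            design = np.column_stack([basis, np.ones_like(basis)])
            coef, *_ = np.linalg.lstsq(design, values, rcond=None)
            inv_m, n0 = coef
            if abs(inv_m) < 1e-12:
                inv_m = 1e-12
            start = np.array([d0, 1.0 / inv_m, p0, n0])
            try:
                res = least_squares(
                    lambda q: _curve(q, sizes) - values,
                    start,
                    bounds=([-np.inf, -np.inf, 1e-6, -np.inf],
                            [s_min - 1e-6, np.inf, np.inf, np.inf]),
                    method="trf",
                    xtol=1e-14, ftol=1e-14, gtol=1e-14,
                )
            except (ValueError, np.linalg.LinAlgError):
                continue
            rss = float(np.sum(res.fun**2))
            if np.isfinite(rss) and (best is None or rss < best[0]):
                best = (rss, res.x)
    if best is None:
        raise RuntimeError("size-curve fit failed from every start (see grid in docs)")
    rss, (d, m, p, n) = best
    return SizeCurveFit(
        d=float(d), m=float(m), p=float(p), n=float(n), rss=rss,
        regime=_classify(float(p)), min_size=float(s_min), max_size=float(sizes.max()),
    )


def select_training_size(
    fit: SizeCurveFit, mode: str, fraction: float | None = None
) -> float:
    """Pick a training-set size (% of the candidate set) from a fitted curve.

    mode="argmax" (maximum regime only): the closed-form stationary point
    s* = d + e^(1/p), clipped to (min tested size, 100].
    mode="target_fraction": the smallest s whose fitted metric reaches
    ``fraction`` of the fitted metric at s = 100, located on a 0.01-resolution
    grid (robust to non-monotone fitted curves).
    """
    if mode == "argmax":
        if fit.regime != "maximum":
            raise ValueError(
                f"argmax needs a maximum regime (p > 1); fitted p = {fit.p:.3g} "
                f"gives {fit.regime}"
            )
        s_star = fit.d + np.exp(1.0 / fit.p)  # always inside the domain (d, 100]
        return float(min(s_star, 100.0))
    if mode == "target_fraction":
        if fraction is None or not 0.0 < fraction <= 1.0:
            raise ValueError("target_fraction mode needs fraction in (0, 1]")
        target = fraction * fit(100.0)
        grid = np.arange(fit.min_size, 100.0 + 1e-9, 0.01)
        reached = np.nonzero(fit(grid) >= target)[0]
        if reached.size == 0:
            return 100.0
        return float(round(grid[reached[0]], 2))
    raise ValueError("mode must be 'argmax' or 'target_fraction'")


def validate_selected_size(sizes_pct, mean_accuracies, selected_size: float) -> float:
    """Interpolated accuracy at the selected size, as a percentage of the
    accuracy at the 100% training-set size."""
    sizes = np.asarray(sizes_pct, dtype=float)
    accs = np.asarray(mean_accuracies, dtype=float)
    order = np.argsort(sizes)
    sizes, accs = sizes[order], accs[order]
    if selected_size < sizes.min() - 1e-9:
        raise ValueError(
            f"selected size {selected_size} below the smallest tested size {sizes.min()}"
        )
    if sizes.max() < 100.0 - 1e-9:
        raise ValueError("validation needs the accuracy at the 100% size")
    at_full = accs[np.argmin(np.abs(sizes - 100.0))]
    interp = float(np.interp(selected_size, sizes, accs))
    return 100.0 * interp / at_full
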