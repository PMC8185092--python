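"""Circular and resampling statistics shared across the pipeline.

Provides the weighted circular-linear regression used to fit trajectory
lines to decoded posteriors (the "slope" of a place-cell sequence or replay
event), the circular-linear correlation coefficient used both as the fit's
r-squared quality measure and for gamma phase-shift analysis, the resultant
vector length for phase locking, Pearson's chi-squared, the multiclass
Matthews correlation coefficient, and seeded percentile bootstrap CIs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "CircLinearFit",
    "circ_linear_fit",
    "circ_linear_corr",
    "resultant_length",
    "circular_distance",
    "pearson_chi2",
    "matthews_multiclass",
    "bootstrap_ci",
]


def circular_distance(a, b):
    """Shortest angular distance between two angles, in [0, pi].

    Accepts scalars or arrays (broadcast).
    """
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % (2 * np.pi)
    return np.minimum(d, 2 * np.pi - d)


def resultant_length(angles) -> float:
    """Mean resultant vector length R of a sample of angles, in [0, 1].

    R = 1 for identical angles (perfect phase locking), R = 0 for a
    balanced/uniform sample.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValueError("resultant_length requires at least one angle")
    return float(np.abs(np.exp(1j * angles).mean()))


def _weighted_corr(x, y, w):
    wsum = w.sum()
    mx = (w * x).sum() / wsum
    my = (w * y).sum() / wsum
    cov = (w * (x - mx) * (y - my)).sum()
    vx = (w * (x - mx) ** 2).sum()
    vy = (w * (y - my) ** 2).sum()
    denom = np.sqrt(vx * vy)
    if denom == 0:
        return 0.0
    return float(cov / denom)


def circ_linear_corr(angles, linear_values, weights=None) -> float:
    """Circular-linear correlation coefficient in [0, 1].

    The standard estimator: with r_xc = corr(x, cos th), r_xs = corr(x, sin th)
    and r_cs = corr(cos th, sin th),

        r = sqrt((r_xc^2 + r_xs^2 - 2 r_xc r_xs r_cs) / (1 - r_cs^2))

    Nonnegative by construction. Optional nonnegative weights give the
    weighted variant used as the fit-quality measure for posterior fits.
    """
    th = np.asarray(angles, dtype=float)
    x = np.asarray(linear_values, dtype=float)
    if th.size < 3:
        raise ValueError("circ_linear_corr requires at least 3 samples")
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    if np.ptp(x[w > 0]) == 0:
        raise ValueError("linear values are constant; correlation undefined")
    c, s = np.cos(th), np.sin(th)
    rxc = _weighted_corr(x, c, w)
    rxs = _weighted_corr(x, s, w)
    rcs = _weighted_corr(c, s, w)
    denom = 1.0 - rcs**2
    if denom <= 0:
        return 0.0
    r2 = (rxc**2 + rxs**2 - 2 * rxc * rxs * rcs) / denom
    return float(np.sqrt(max(r2, 0.0)))


@dataclass(frozen=True)
class CircLinearFit:
    """Result of a weighted circular-linear regression theta ~ a*t + phi0.

    slope : rad per unit of the linear variable (rad/s for time fits,
        rad per cycle for gamma cycle-number fits).
    phi0 : phase offset in radians (angle of the resultant at the optimum).
    r2 : squared weighted circular-linear correlation between the angles and
        the linear variable, in [0, 1].
    resultant : weighted mean resultant length R at the fitted slope.
    """

    slope: float
    phi0: float
    r2: float
    resultant: float

    @property
    def sign(self) -> str:
        return "positive" if self.slope >= 0 else "negative"

    def predict(self, t):
        return (self.slope * np.asarray(t, dtype=float) + self.phi0) % (2 * np.pi)


def _resultant_at(slope, t, th, w):
    z = np.sum(w * np.exp(1j * (th - slope * t)))
    return np.abs(z) / np.sum(w)


def circ_linear_fit(
    t,
    angles,
    weights=None,
    slope_range=(-20.0, 20.0),
    n_grid=101,
) -> CircLinearFit:
    """Fit a line on the cylinder by maximizing the weighted resultant length.

    Maximizes R(a) = |sum w exp(i(theta - a t))| / sum w over a dense slope
    grid on ``slope_range`` and refines the best grid point with bounded
    scalar optimization within one grid step. phi0 is the argument of the
    resultant at the optimum, so the fitted line theta = a t + phi0 passes
    through the weighted circular mass.
    """
    t = np.asarray(t, dtype=float)
    th = np.asarray(angles, dtype=float)
    w = np.ones_like(t) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    if w.sum() <= 0:
        raise ValueError("all weights are zero")
    lo, hi = map(float, slope_range)
    if not np.isfinite([lo, hi]).all() or hi <= lo:
        raise ValueError("slope_range must be a finite (lo, hi) with hi > lo")

    grid = np.linspace(lo, hi, n_grid)
    # R on the grid, vectorized: (n_grid, n_samples)
    phase = th[None, :] - grid[:, None] * t[None, :]
    r_grid = np.abs((w[None, :] * np.exp(1j * phase)).sum(axis=1)) / w.sum()
    k = int(np.argmax(r_grid))
    step = grid[1] - grid[0]
    a_lo = max(lo, grid[k] - step)
    a_hi = min(hi, grid[k] + step)
    res = optimize.minimize_scalar(
        lambda a: -_resultant_at(a, t, th, w),
        bounds=(a_lo, a_hi),
        method="bounded",
        options={"xatol": 1e-6 * max(1.0, step)},
    )
    slope = float(res.x)
    big_r = _resultant_at(slope, t, th, w)
    if big_r < r_grid[k]:  # refinement should never lose to the grid
        slope, big_r = float(grid[k]), float(r_grid[k])
    z = np.sum(w * np.exp(1j * (th - slope * t)))
    phi0 = float(np.angle(z) % (2 * np.pi))
    try:
        r = circ_linear_corr(th, t, weights=w)
    except ValueError:
        r = 0.0
    return CircLinearFit(slope=slope, phi0=phi0, r2=r**2, resultant=float(big_r))


def pearson_chi2(table):
    """Pearson chi-squared test of independence, no continuity correction.

    Returns (chi2, df, p). For the 2x2 tables used here df = 1.
    """
    obs = np.asarray(table, dtype=float)
    if np.any(obs < 0) or obs.sum() <= 0:
        raise ValueError("table must be nonnegative with a positive total")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("table has a zero marginal")
    chi2, p, df, _ = stats.chi2_contingency(obs, correction=False)
    return float(chi2), int(df), float(p)


def matthews_multiclass(confusion):
    """Multiclass Matthews correlation coefficient from a K x K confusion matrix.

    Uses the covariance form: with c = trace, s = total, p_k = predicted
    marginals, t_k = true marginals,

        MCC = (c*s - p.t) / sqrt((s^2 - p.p) * (s^2 - t.t))

    Reduces to the binary phi coefficient for K = 2. Returns NaN when a
    marginal is degenerate (coefficient undefined), never silently 0.
    """
    cm = np.asarray(confusion, dtype=float)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    s = cm.sum()
    if s <= 0:
        raise ValueError("confusion matrix total must be positive")
    c = np.trace(cm)
    t_k = cm.sum(axis=1)
    p_k = cm.sum(axis=0)
    denom2 = (s**2 - p_k @ p_k) * (s**2 - t_k @ t_k)
    if denom2 <= 0:
        return float("nan")
    return float((c * s - p_k @ t_k) / np.sqrt(denom2))


def bootstrap_ci(values, statistic=np.mean, n_resamples=5000, level=0.95, seed=0):
    """Seeded percentile bootstrap confidence interval.

    Resamples ``values`` with replacement ``n_resamples`` times, applies
    ``statistic`` to each resample, and returns the percentile interval at
    the requested level.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 1:
        raise ValueError("bootstrap_ci requires at least one value")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_resamples, values.size))
    boot = np.apply_along_axis(statistic, 1, values[idx])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(boot, [alpha, 1.0 - alpha])
    return float(lo), float(hi)
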