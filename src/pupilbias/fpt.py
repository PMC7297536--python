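"""Analytic first-passage results for the Wiener diffusion between two
absorbing bounds.

The decision variable follows dX = mu dt + s dW, starting at z = w*a between
a lower bound at 0 and an upper bound at a.  All closed forms below use the
convention s = 1 unless stated; callers can rescale (mu, a, z divided by s).

The first-passage density uses the two classical series expansions (a
small-time and a large-time representation), switching per evaluation point
to whichever converges faster -- the standard approach for drift-diffusion
likelihoods.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "prob_upper",
    "mean_decision_time_zero_drift",
    "fpt_density_lower",
    "fpt_density_upper",
    "fpt_cdf_grid",
    "defective_cdfs",
]


def prob_upper(v: float, a: float, z: float, s: float = 1.0) -> float:
    """Probability of absorption at the upper bound.

    P(upper) = (1 - exp(-2 v z / s^2)) / (1 - exp(-2 v a / s^2)); z/a in the
    zero-drift limit.
    """
    if a <= 0 or not 0 <= z <= a:
        raise ValueError("require a > 0 and 0 <= z <= a")
    k = 2.0 * v / s**2
    if abs(k * a) < 1e-9:
        return z / a
    # guard against overflow for strongly negative drift
    num = -np.expm1(-k * z)
    den = -np.expm1(-k * a)
    return float(num / den)


def mean_decision_time_zero_drift(a: float, z: float, s: float = 1.0) -> float:
    """Mean absorption time for zero drift: z (a - z) / s^2."""
    return z * (a - z) / s**2


def _f_lower_unit(tn: np.ndarray, w: float, k_small: int = 7, k_large: int = 7) -> np.ndarray:
    """Density of lower-bound passage for a = 1, v = 0, start w, at scaled
    times tn = t / a^2.  Chooses the small- or large-time series pointwise."""
    tn = np.asarray(tn, dtype=float)
    out = np.zeros_like(tn)
    pos = tn > 0
    t = tn[pos]

    small = t < 0.35
    # small-time series: sum over image charges
    if np.any(small):
        ts = t[small]
        ks = np.arange(-k_small, k_small + 1)
        arg = w + 2.0 * ks[:, None]
        val = (arg * np.exp(-(arg**2) / (2.0 * ts[None, :]))).sum(axis=0)
        res_s = val / np.sqrt(2.0 * np.pi * ts**3)
    # large-time series: spectral expansion
    if np.any(~small):
        tl = t[~small]
        kl = np.arange(1, k_large + 1)
        val = (
            kl[:, None]
            * np.exp(-(kl[:, None] ** 2) * np.pi**2 * tl[None, :] / 2.0)
            * np.sin(kl[:, None] * np.pi * w)
        ).sum(axis=0)
        res_l = np.pi * val

    res = np.empty_like(t)
    if np.any(small):
        res[small] = res_s
    if np.any(~small):
        res[~small] = res_l
    out[pos] = np.maximum(res, 0.0)
    return out


def fpt_density_lower(t: np.ndarray, v: float, a: float, w: float, s: float = 1.0) -> np.ndarray:
    """First-passage density through the LOWER bound at times t.

    f(t) = (1/a^2) exp(-v a w - v^2 t / 2) f1(t/a^2; w) after rescaling to
    unit noise.
    """
    t = np.asarray(t, dtype=float)
    v_, a_, w_ = v / s, a / s, w
    tn = t / a_**2
    expo = -v_ * a_ * w_ - 0.5 * v_**2 * t
    # clip exponent to dodge overflow for extreme drifts; density ~ 0 there
    return _f_lower_unit(tn, w_) / a_**2 * np.exp(np.clip(expo, -700, 700))


def fpt_density_upper(t: np.ndarray, v: float, a: float, w: float, s: float = 1.0) -> np.ndarray:
    """First-passage density through the UPPER bound (mirror of the lower)."""
    return fpt_density_lower(t, -v, a, 1.0 - w, s=s)


def fpt_cdf_grid(
    t_grid: np.ndarray,
    v: float,
    a: float,
    w: float,
    s: float = 1.0,
    sv: float = 0.0,
    n_quad: int = 12,
):
    """Defective CDFs of the first-passage time at each bound on a time grid.

    Drift-rate variability sv (trial-to-trial sd of v) is marginalised by
    Gauss-Hermite quadrature.  Returns (F_lower, F_upper), cumulative
    trapezoid integrals of the respective densities; F_lower(inf)+F_upper(inf)
    = 1 up to grid truncation.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if sv > 1e-12:
        nodes, weights = np.polynomial.hermite_e.hermegauss(n_quad)
        drifts = v + sv * nodes
        wts = weights / np.sqrt(2.0 * np.pi)
    else:
        drifts = np.array([v])
        wts = np.array([1.0])
    # the series part is drift-independent: evaluate once per bound, then
    # apply the drift-dependent exponential tilt for all quadrature nodes
    a_, w_ = a / s, w
    tn = t_grid / a_**2
    unit_lo = _f_lower_unit(tn, w_) / a_**2
    unit_up = _f_lower_unit(tn, 1.0 - w_) / a_**2
    d_ = drifts[:, None] / s
    expo_lo = np.exp(np.clip(-d_ * a_ * w_ - 0.5 * d_**2 * t_grid[None, :], -700, 700))
    expo_up = np.exp(np.clip(d_ * a_ * (1.0 - w_) - 0.5 * d_**2 * t_grid[None, :], -700, 700))
    f_lo = (wts @ expo_lo) * unit_lo
    f_up = (wts @ expo_up) * unit_up
    dt = np.diff(t_grid)
    F_lo = np.concatenate([[0.0], np.cumsum(0.5 * (f_lo[1:] + f_lo[:-1]) * dt)])
    F_up = np.concatenate([[0.0], np.cumsum(0.5 * (f_up[1:] + f_up[:-1]) * dt)])
    return F_lo, F_up


def default_time_grid(t_max: float = 10.0) -> np.ndarray:
    """Nonuniform grid, dense at short times where the density peaks."""
    early = np.arange(0.0, 1.5, 0.0015)
    late = np.arange(1.5, t_max + 1e-9, 0.01)
    return np.concatenate([early, late])


def defective_cdfs(
    edges_lower: np.ndarray,
    edges_upper: np.ndarray,
    v: float,
    a: float,
    w: float,
    t0: float,
    s: float = 1.0,
    sv: float = 0.0,
    t_grid: np.ndarray | None = None,
):
    """Evaluate the defective first-passage CDFs at RT edges (RT = T + t0).

    Returns (F_lower(edges_lower), F_upper(edges_upper), P_lower_total,
    P_upper_total).  The totals are the grid-truncated absorption
    probabilities at each bound.
    """
    if t_grid is None:
        t_grid = default_time_grid()
    F_lo, F_up = fpt_cdf_grid(t_grid, v, a, w, s=s, sv=sv)
    e_lo = np.clip(np.asarray(edges_lower, dtype=float) - t0, 0.0, t_grid[-1])
    e_up = np.clip(np.asarray(edges_upper, dtype=float) - t0, 0.0, t_grid[-1])
    return (
        np.interp(e_lo, t_grid, F_lo),
        np.interp(e_up, t_grid, F_up),
        float(F_lo[-1]),
        float(F_up[-1]),
    )
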