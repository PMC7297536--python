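"""Signal-detection metrics, including the composite-distribution overall
bias used when one decision criterion serves multiple signal strengths.

In a detection task with several signal loudness levels but a single
criterion, per-level criteria c_i are all expressions of the same underlying
choice point.  The overall bias is defined against a composite signal
distribution S(x) = mean_i N(d_i, 1) and the noise distribution N(0, 1):

    zero-bias point Z : the evidence value where S and N cross,
    choice point    C : 0.5 * d_i + c_i (identical across i for a shared
                        false-alarm rate),
    overall bias      : C - Z   (positive = conservative).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats


@dataclass
class SDTMetrics:
    d_prime: float
    criterion: float
    hit_rate: float
    fa_rate: float


@dataclass
class CompositeBiasResult:
    zero_bias_point: float
    choice_point: float
    overall_bias: float
    composite_components: list


def sdt_d_prime_criterion(n_hit: int, n_miss: int, n_fa: int, n_cr: int) -> SDTMetrics:
    """d' and criterion from raw counts.

    Rates are corrected with the log-linear rule (+0.5 per cell) so that
    extreme rates of 0 or 1 stay finite under the probit transform.
    d' = z(HR) - z(FAR); c = -(z(HR) + z(FAR)) / 2.
    """
    n_signal = n_hit + n_miss
    n_noise = n_fa + n_cr
    if n_signal == 0 or n_noise == 0:
        raise ValueError("each stimulus class needs at least one trial")
    hr = (n_hit + 0.5) / (n_signal + 1.0)
    far = (n_fa + 0.5) / (n_noise + 1.0)
    zh, zf = stats.norm.ppf(hr), stats.norm.ppf(far)
    return SDTMetrics(
        d_prime=float(zh - zf),
        criterion=float(-(zh + zf) / 2.0),
        hit_rate=float(hr),
        fa_rate=float(far),
    )


def composite_overall_bias(
    metrics: Sequence[SDTMetrics], tol_c: float = 1e-6
) -> CompositeBiasResult:
    """Overall bias from per-loudness SDT metrics that share one FAR.

    The composite signal density is the average of unit-variance normals at
    the per-loudness d_i.  Z is the crossing of the composite and the noise
    density, located by bisection; if several crossings exist the one nearest
    mean(d_i)/2 is taken.  C = 0.5 d_i + c_i must agree across loudness
    levels (it does exactly when all metrics derive from one false-alarm
    rate).
    """
    d = np.array([m.d_prime for m in metrics], dtype=float)
    c = np.array([m.criterion for m in metrics], dtype=float)
    if np.all(d <= 0):
        raise ValueError("composite bias undefined: all d_i <= 0")
    C_all = 0.5 * d + c
    if np.ptp(C_all) > tol_c:
        raise ValueError(
            "inconsistent inputs: choice point differs across loudness levels "
            "(criteria must derive from a shared false-alarm rate)"
        )
    C = float(C_all.mean())

    def diff(x):
        return np.mean(stats.norm.pdf(x - d)) - stats.norm.pdf(x)

    lo = float(d.min() / 2.0 - 3.0)
    hi = float(d.max() / 2.0 + 3.0)
    grid = np.linspace(lo, hi, 2001)
    vals = np.array([diff(x) for x in grid])
    target = float(np.mean(d) / 2.0)
    exact = np.nonzero(vals == 0.0)[0]
    sign_changes = np.nonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)[0]
    candidates = [(abs(grid[i] - target), float(grid[i]), None) for i in exact]
    candidates += [
        (abs(0.5 * (grid[i] + grid[i + 1]) - target), None, i) for i in sign_changes
    ]
    if not candidates:
        raise ValueError("no crossing of composite-signal and noise densities found")
    _, z_exact, i = min(candidates, key=lambda c: c[0])
    if z_exact is not None:
        Z = z_exact
    else:
        Z = float(optimize.bisect(diff, grid[i], grid[i + 1], xtol=1e-10))
    return CompositeBiasResult(
        zero_bias_point=Z,
        choice_point=C,
        overall_bias=C - Z,
        composite_components=list(d),
    )


def bias_shift_metrics(per_bin_bias: Sequence[float], overall_bias: float) -> dict:
    """Pupil-linked bias-shift summaries for one subject.

    Returns the high-minus-low bin difference, a least-squares slope over
    bin index, per-bin |bias|, and a sign-flipped copy of the per-bin values
    for overall-liberal subjects (overall bias < 0) so that suppression of
    either-signed bias maps onto a common reduction-toward-zero axis.
    """
    b = np.asarray(per_bin_bias, dtype=float)
    if b.size < 2:
        raise ValueError("need at least two pupil bins")
    x = np.arange(b.size, dtype=float)
    slope = float(np.polyfit(x, b, 1)[0])
    flip = -1.0 if overall_bias < 0 else 1.0
    return {
        "shift_high_minus_low": float(b[-1] - b[0]),
        "slope": slope,
        "abs_bias": np.abs(b),
        "signed_toward_zero": flip * b,
        "abs_drop_high_vs_low": float(abs(b[0]) - abs(b[-1])),
    }
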