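"""Drift-diffusion simulation and quantile-based (G-square) fitting.

The model: a decision variable starts at z = z_rel * a between an upper
bound (yes) and a lower bound (no/no-go) and drifts with rate
mu = +/- v(loudness) + v_bias, perturbed by within-trial Gaussian noise of
sd ``s`` (convention s = 1) and, optionally, trial-to-trial drift
variability sv.  RT = first-passage time + non-decision time t0.

Urgency is implemented as hyperbolically collapsing bounds

    a_up(t)   = clamp(a - a*t/(t + tau), a/2, a)
    a_down(t) = clamp(a*t/(t + tau), 0, a/2)

so the bounds meet exactly at a/2 at t = tau, forcing termination.

Fitting follows the quantile maximum-likelihood ("G square") approach: RT
distributions are summarised by the 0.1/0.3/0.5/0.7/0.9 quantiles, observed
bin counts are compared against model-expected bin probabilities with
G^2 = 2 sum O ln(O/E), and for go/no-go data a single bin holds the no-go
count.  Expected probabilities come from the analytic first-passage solution
when bounds are constant, and from common-random-number simulation when they
collapse.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from numba import njit
from scipy import optimize

from . import fpt

QUANTILE_PROBS = (0.1, 0.3, 0.5, 0.7, 0.9)


# ---------------------------------------------------------------------------
# parameter containers


@dataclass
class DDMParams:
    """Generative/fitted diffusion parameters.

    v maps loudness level -> drift magnitude (a plain float is broadcast);
    noise trials accumulate drift -v_noise + v_bias.
    """

    v: float | Mapping[object, float] = 1.0
    v_bias: float = 0.0
    z_rel: float = 0.5
    a: float = 1.0
    t0: float = 0.3
    sv: float = 0.0
    s: float = 1.0
    tau_urgency: float | None = None
    v_noise: float | None = None  # drift magnitude on noise trials; default = v

    def drift_for(self, signal: bool, loudness=None) -> float:
        if signal:
            v = self.v[loudness] if isinstance(self.v, Mapping) else self.v
            return v + self.v_bias
        vn = self.v_noise
        if vn is None:
            vn = (
                float(np.mean(list(self.v.values())))
                if isinstance(self.v, Mapping)
                else self.v
            )
        return -vn + self.v_bias

    def validate(self) -> None:
        if self.a <= 0:
            raise ValueError("boundary separation a must be > 0")
        if not 0 < self.z_rel < 1:
            raise ValueError("z_rel must lie in (0, 1)")
        if self.t0 < 0:
            raise ValueError("non-decision time must be >= 0")
        if self.sv < 0:
            raise ValueError("drift variability sv must be >= 0")
        if self.tau_urgency is not None and self.tau_urgency <= 0:
            raise ValueError("tau_urgency must be > 0 when present")


@dataclass
class BoundSpec:
    a: float
    tau_urgency: float | None = None


def bound_trajectory(bounds: BoundSpec, t) -> tuple[np.ndarray, np.ndarray]:
    """Upper and lower bound position(s) at time(s) t >= 0."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    a = bounds.a
    if bounds.tau_urgency is None:
        return np.full_like(t, a), np.zeros_like(t)
    tau = bounds.tau_urgency
    collapse = a * t / (t + tau)
    a_up = np.clip(a - collapse, a / 2.0, a)
    a_down = np.clip(collapse, 0.0, a / 2.0)
    return a_up, a_down


# ---------------------------------------------------------------------------
# simulator


@njit(cache=True)
def _simulate_paths(drifts, z0, a, tau, s, dt, t_max, seed):  # pragma: no cover - numba
    n = drifts.shape[0]
    choices = np.empty(n, dtype=np.int8)
    rts = np.empty(n, dtype=np.float64)
    np.random.seed(seed)
    sq = s * np.sqrt(dt)
    has_tau = tau > 0.0
    half = a / 2.0
    for i in range(n):
        mu = drifts[i]
        x = z0
        t = 0.0
        choice = np.int8(-1)
        while t < t_max:
            if has_tau and t >= tau:
                # bounds have met at a/2: forced termination
                if x > half:
                    choice = 1
                elif x < half:
                    choice = 0
                else:
                    choice = np.int8(1) if np.random.random() < 0.5 else np.int8(0)
                break
            if has_tau:
                c = a * t / (t + tau)
                b_up = a - c
                if b_up < half:
                    b_up = half
                b_lo = c
                if b_lo > half:
                    b_lo = half
            else:
                b_up = a
                b_lo = 0.0
            x_new = x + mu * dt + sq * np.random.standard_normal()
            t += dt
            # crossing times are interpolated within the step: discretising
            # RTs to the step grid visibly distorts the fast tail of the
            # first-passage distribution at large trial counts
            if x_new >= b_up:
                choice = 1
                t += dt * ((b_up - x) / (x_new - x) - 1.0)
                break
            if x_new <= b_lo:
                choice = 0
                t += dt * ((b_lo - x) / (x_new - x) - 1.0)
                break
            # Brownian-bridge probability of an unobserved crossing; skip
            # the exp when both endpoints sit > 4 sd from the bound
            # (crossing probability < e^-32)
            far = 4.0 * sq
            if (b_up - x) < far or (b_up - x_new) < far:
                p_up = np.exp(-2.0 * (b_up - x) * (b_up - x_new) / (s * s * dt))
                if np.random.random() < p_up:
                    choice = 1
                    t += dt * (np.random.random() - 1.0)
                    break
            if (x - b_lo) < far or (x_new - b_lo) < far:
                p_lo = np.exp(-2.0 * (x - b_lo) * (x_new - b_lo) / (s * s * dt))
                if np.random.random() < p_lo:
                    choice = 0
                    t += dt * (np.random.random() - 1.0)
                    break
            x = x_new
        choices[i] = choice
        rts[i] = t
    return choices, rts


def simulate_ddm(
    params: DDMParams,
    n_trials: int | None = None,
    signal: np.ndarray | None = None,
    loudness: np.ndarray | None = None,
    seed: int = 0,
    dt: float = 0.001,
    t_max: float = 10.0,
    drifts: np.ndarray | None = None,
):
    """Simulate choices and RTs via Euler-Maruyama with bridge correction.

    Either pass per-trial ``drifts`` directly, or ``signal`` (+ optional
    ``loudness``) flags from which drifts are built as +/-v + v_bias.
    Returns (choices, rts): choice 1 = upper/yes, 0 = lower/no, -1 = censored
    at t_max (constant bounds only); rts include t0 and are NaN for censored
    trials.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    if drifts is None:
        if signal is None:
            if n_trials is None:
                raise ValueError("need n_trials, signal flags, or explicit drifts")
            signal = np.ones(n_trials, dtype=bool)
        signal = np.asarray(signal, dtype=bool)
        if loudness is None:
            loudness = np.full(signal.shape, None, dtype=object)
        drifts = np.array(
            [params.drift_for(sg, lo) for sg, lo in zip(signal, loudness)],
            dtype=float,
        )
    else:
        drifts = np.asarray(drifts, dtype=float).copy()
    if params.sv > 0:
        drifts = drifts + params.sv * rng.standard_normal(drifts.shape[0])
    tau = params.tau_urgency if params.tau_urgency is not None else 0.0
    sub = int(rng.integers(0, 2**31 - 1))
    choices, dec_t = _simulate_paths(
        drifts,
        params.z_rel * params.a,
        params.a,
        float(tau),
        params.s,
        dt,
        t_max,
        sub,
    )
    rts = dec_t + params.t0
    rts[choices < 0] = np.nan
    return choices, rts


def sample_ddm_exact(
    params: DDMParams,
    drifts: np.ndarray,
    seed: int = 0,
    t_res: float = 0.0003,
    t_max: float = 12.0,
):
    """Exact-in-distribution sampling of (choice, RT) for constant bounds.

    Draws first-passage outcomes by inverting the analytic defective CDFs on
    a fine time grid (resolution ``t_res`` with linear interpolation within
    cells), avoiding path-discretisation error entirely.  Only available for
    constant bounds and sv = 0 (per-trial drifts may still differ, e.g.
    through an external drift-bias map); collapsing bounds or drift
    variability need the path simulator.
    """
    params.validate()
    if params.tau_urgency is not None:
        raise ValueError("exact sampling requires constant bounds")
    if params.sv > 0:
        raise ValueError("exact sampling requires sv = 0; add variability via drifts")
    drifts = np.asarray(drifts, dtype=float)
    rng = np.random.default_rng(seed)
    grid = np.concatenate(
        [np.arange(0.0, 2.5, t_res), np.arange(2.5, t_max, 0.005)]
    )
    choices = np.empty(drifts.size, dtype=np.int8)
    rts = np.empty(drifts.size, dtype=float)
    w = params.z_rel
    for d in np.unique(drifts):
        sel = np.nonzero(drifts == d)[0]
        F_lo, F_up = fpt.fpt_cdf_grid(grid, d / params.s, params.a / params.s, w)
        tot = F_lo[-1] + F_up[-1]
        u = rng.uniform(0.0, tot, sel.size)
        is_up = u < F_up[-1]
        t_up = np.interp(u[is_up], F_up, grid)
        t_lo = np.interp(u[~is_up] - F_up[-1], F_lo, grid)
        choices[sel[is_up]] = 1
        choices[sel[~is_up]] = 0
        rts[sel[is_up]] = t_up
        rts[sel[~is_up]] = t_lo
    return choices, rts + params.t0


# ---------------------------------------------------------------------------
# quantiles, G-square, CRF


def rt_quantiles(rts, probs: Sequence[float] = QUANTILE_PROBS) -> np.ndarray:
    """Quantile edges of an RT sample (linear-interpolated order statistics).

    Fewer RTs than requested quantiles collapses to the median with a
    warning; callers then get coarser bins rather than an error.
    """
    rts = np.asarray(rts, dtype=float)
    rts = rts[np.isfinite(rts)]
    if rts.size == 0:
        raise ValueError("no finite RTs")
    if rts.size < len(probs):
        import warnings

        warnings.warn("too few RTs for requested quantiles; collapsing to median")
        return np.quantile(rts, [0.5])
    return np.quantile(rts, list(probs))


def gsquare_statistic(observed, expected_prop) -> float:
    """G^2 = 2 sum O ln(O / (N p)), with 0 ln 0 = 0 and p floored at 1e-10."""
    o = np.asarray(observed, dtype=float)
    if np.any(o < 0):
        raise ValueError("negative counts")
    p = np.maximum(np.asarray(expected_prop, dtype=float), 1e-10)
    n = o.sum()
    e = n * p
    mask = o > 0
    return float(2.0 * np.sum(o[mask] * np.log(o[mask] / e[mask])))


def conditional_response_function(choices, rts, n_bins: int = 5) -> np.ndarray:
    """Fraction of yes (upper-bound) choices per pooled-RT quantile bin."""
    choices = np.asarray(choices)
    rts = np.asarray(rts, dtype=float)
    ok = np.isfinite(rts) & (choices >= 0)
    choices, rts = choices[ok], rts[ok]
    if rts.size < n_bins:
        raise ValueError("need at least n_bins trials with RTs")
    edges = np.quantile(rts, np.linspace(0, 1, n_bins + 1))
    edges[0] -= 1e-9
    idx = np.clip(np.searchsorted(edges, rts, side="left") - 1, 0, n_bins - 1)
    return np.array([choices[idx == b].mean() for b in range(n_bins)])


# ---------------------------------------------------------------------------
# observed / expected bin machinery


def _bin_counts_from_edges(rts, edges) -> np.ndarray:
    """Counts in the len(edges)+1 bins delimited by quantile edges."""
    rts = np.asarray(rts, dtype=float)
    return np.histogram(rts, bins=np.concatenate([[-np.inf], edges, [np.inf]]))[0]


def observed_cell(choices, rts, task_kind: str = "yesno"):
    """Summarise one condition cell into quantile-bin counts.

    yes/no: 6 yes-RT bins + 6 no-RT bins (each from that choice's own
    quantiles).  go/no-go: 6 yes-RT bins + 1 bin counting no-go trials.
    Returns dict with counts, edges and n.
    """
    choices = np.asarray(choices)
    rts = np.asarray(rts, dtype=float)
    n = choices.size
    yes = choices == 1
    yes_rts = rts[yes & np.isfinite(rts)]
    edges_yes = rt_quantiles(yes_rts) if yes_rts.size >= 5 else np.array([])
    counts_yes = (
        _bin_counts_from_edges(yes_rts, edges_yes)
        if edges_yes.size
        else np.array([yes_rts.size])
    )
    if task_kind == "gonogo":
        n_nogo = int(np.sum(choices != 1))
        return {
            "counts": np.concatenate([counts_yes, [n_nogo]]),
            "edges_yes": edges_yes,
            "edges_no": np.array([]),
            "n": n,
        }
    no = choices == 0
    no_rts = rts[no & np.isfinite(rts)]
    edges_no = rt_quantiles(no_rts) if no_rts.size >= 5 else np.array([])
    counts_no = (
        _bin_counts_from_edges(no_rts, edges_no)
        if edges_no.size
        else np.array([no_rts.size])
    )
    return {
        "counts": np.concatenate([counts_yes, counts_no]),
        "edges_yes": edges_yes,
        "edges_no": edges_no,
        "n": n,
    }


def expected_props_analytic(cell, params: DDMParams, drift: float) -> np.ndarray:
    """Expected bin probabilities from the analytic first-passage solution."""
    if params.tau_urgency is not None:
        raise ValueError("analytic expectations require constant bounds")
    w = params.z_rel
    F_no, F_yes, P_no, P_yes = fpt.defective_cdfs(
        cell["edges_no"],
        cell["edges_yes"],
        drift,
        params.a / params.s,
        w,
        params.t0,
        sv=params.sv / params.s,
    )
    # note: drift and a rescaled by s so the unit-noise solution applies
    def binify(F_edges, total):
        if F_edges.size == 0:
            return np.array([total])
        return np.diff(np.concatenate([[0.0], F_edges, [total]]))

    p_yes_bins = binify(F_yes, P_yes)
    task_kind = cell.get("task_kind", "yesno")
    if task_kind == "gonogo":
        return np.concatenate([p_yes_bins, [max(1.0 - P_yes, 0.0)]])
    p_no_bins = binify(F_no, P_no)
    return np.concatenate([p_yes_bins, p_no_bins])


def expected_props_simulated(
    cell, params: DDMParams, drift: float, n_sim: int = 10000, seed: int = 12345
) -> np.ndarray:
    """Expected bin probabilities by forward simulation (common random
    numbers across optimiser iterations via the fixed seed)."""
    choices, rts = simulate_ddm(
        params, drifts=np.full(n_sim, drift), seed=seed, dt=0.002
    )
    yes = choices == 1
    yes_rts = rts[yes & np.isfinite(rts)]
    e_yes = cell["edges_yes"]
    c_yes = (
        _bin_counts_from_edges(yes_rts, e_yes) if e_yes.size else np.array([yes_rts.size])
    )
    task_kind = cell.get("task_kind", "yesno")
    if task_kind == "gonogo":
        n_nogo = np.sum(choices != 1)
        return np.concatenate([c_yes, [n_nogo]]) / n_sim
    no_rts = rts[(choices == 0) & np.isfinite(rts)]
    e_no = cell["edges_no"]
    c_no = _bin_counts_from_edges(no_rts, e_no) if e_no.size else np.array([no_rts.size])
    return np.concatenate([c_yes, c_no]) / n_sim


# ---------------------------------------------------------------------------
# fitting


@dataclass
class ModelSpec:
    """Which parameters are free, and which vary by condition.

    free: parameter names fitted as a single shared value.
    by_condition: parameter names fitted separately per condition level.
    fixed: mapping name -> frozen value (overrides base params).
    """

    free: tuple = ("v", "a", "t0")
    by_condition: tuple = ("v_bias",)
    fixed: dict = field(default_factory=dict)

    def n_params(self, n_conditions: int) -> int:
        return len(self.free) + len(self.by_condition) * n_conditions


@dataclass
class FitResult:
    params: DDMParams
    per_condition: dict
    gsq: float
    n_trials: int
    k_params: int
    bic: float
    converged: bool
    observed_bins: dict
    expected_bins: dict


_BOUNDS = {
    "v": (0.01, 8.0),
    "a": (0.2, 5.0),
    "t0": (0.01, 1.5),
    "sv": (0.0, 3.0),
    "v_bias": (-4.0, 4.0),
    "z_rel": (0.05, 0.95),
    "tau_urgency": (0.05, 10.0),
}

_DEFAULT_INIT = {
    "v": 1.0,
    "a": 1.2,
    "t0": 0.25,
    "sv": 0.3,
    "v_bias": 0.0,
    "z_rel": 0.5,
    "tau_urgency": 1.5,
}


def _build_cells(trials, task_kind):
    """Group a trial table into (condition, stimulus) cells with observed
    quantile-bin counts."""
    import pandas as pd

    trials = pd.DataFrame(trials)
    if "condition" not in trials:
        trials = trials.assign(condition=0)
    cells = []
    cond_levels = sorted(trials["condition"].unique())
    for cond in cond_levels:
        sub = trials[trials["condition"] == cond]
        for sig in sorted(sub["signal"].unique()):
            ss = sub[sub["signal"] == sig]
            cell = observed_cell(ss["choice"].to_numpy(), ss["rt"].to_numpy(), task_kind)
            cell["condition"] = cond
            cell["signal"] = bool(sig)
            cell["task_kind"] = task_kind
            cells.append(cell)
    return cells, cond_levels


def _unpack(theta, spec: ModelSpec, cond_levels, base: DDMParams):
    vals = dict(spec.fixed)
    i = 0
    for name in spec.free:
        vals[name] = theta[i]
        i += 1
    per_cond = {}
    for name in spec.by_condition:
        for c in cond_levels:
            per_cond.setdefault(c, {})[name] = theta[i]
            i += 1
    shared = {k: v for k, v in vals.items() if k in DDMParams.__dataclass_fields__}
    return replace(base, **shared), per_cond


def _objective(theta, cells, spec, cond_levels, base, use_sim, n_sim, sim_seed):
    # soft box constraints: reject out-of-bounds proposals
    i = 0
    for name in spec.free:
        lo, hi = _BOUNDS[name]
        if not lo <= theta[i] <= hi:
            return 1e12
        i += 1
    for name in spec.by_condition:
        lo, hi = _BOUNDS[name]
        for _ in cond_levels:
            if not lo <= theta[i] <= hi:
                return 1e12
            i += 1
    params, per_cond = _unpack(theta, spec, cond_levels, base)
    total = 0.0
    for cell in cells:
        p = params
        overrides = per_cond.get(cell["condition"], {})
        if overrides:
            p = replace(params, **overrides)
        try:
            p.validate()
        except ValueError:
            return 1e12
        drift = p.drift_for(cell["signal"])
        try:
            if use_sim:
                props = expected_props_simulated(cell, p, drift, n_sim=n_sim, seed=sim_seed)
            else:
                props = expected_props_analytic(cell, p, drift)
        except (ValueError, FloatingPointError):
            return 1e12
        total += gsquare_statistic(cell["counts"], props)
    if not np.isfinite(total):
        return 1e12
    return total


def _initial_guess(trials, spec: ModelSpec, cond_levels):
    """Crude data-driven start: t0 just under the fastest RT, defaults
    elsewhere."""
    import pandas as pd

    trials = pd.DataFrame(trials)
    rts = trials["rt"].to_numpy(dtype=float)
    rts = rts[np.isfinite(rts)]
    t0_guess = max(0.05, float(np.quantile(rts, 0.005)) * 0.85) if rts.size else 0.25
    init = dict(_DEFAULT_INIT)
    init["t0"] = min(t0_guess, _BOUNDS["t0"][1])
    theta = [init[name] for name in spec.free]
    for name in spec.by_condition:
        theta.extend([init[name]] * len(cond_levels))
    return np.array(theta)


def fit_ddm_quantile(
    trials,
    spec: ModelSpec | None = None,
    task_kind: str = "yesno",
    seed: int = 0,
    base_params: DDMParams | None = None,
    n_restarts: int = 3,
    n_sim: int = 10000,
    maxiter: int | None = None,
) -> FitResult:
    """Fit diffusion parameters by minimising summed G^2 over condition cells.

    ``trials`` is a table with columns signal (0/1), choice (1 yes / 0 no or
    no-go), rt (NaN allowed for no-go), and optionally condition.  Uses the
    analytic first-passage solution for constant-bound models and
    common-random-number simulation when tau_urgency is free or fixed.
    """
    spec = spec or ModelSpec()
    base = base_params or DDMParams()
    cells, cond_levels = _build_cells(trials, task_kind)
    n_total = int(sum(c["n"] for c in cells))
    use_sim = "tau_urgency" in spec.free or "tau_urgency" in spec.by_condition or (
        spec.fixed.get("tau_urgency") is not None
    )
    rng = np.random.default_rng(seed)
    sim_seed = int(rng.integers(0, 2**31 - 1))
    x0 = _initial_guess(trials, spec, cond_levels)
    args = (cells, spec, cond_levels, base, use_sim, n_sim, sim_seed)
    best = None
    if maxiter is None:
        maxiter = 400 * len(x0)
    opts = {"maxiter": maxiter, "xatol": 1e-5, "fatol": 1e-6, "adaptive": True}
    for r in range(n_restarts):
        start = x0 if r == 0 else x0 * (1 + 0.15 * rng.standard_normal(x0.size)) + 0.05 * rng.standard_normal(x0.size)
        res = optimize.minimize(
            _objective, start, args=args, method="Nelder-Mead", options=opts
        )
        if best is None or res.fun < best.fun:
            best = res
    # polish: restart the simplex at the incumbent to escape degeneracy
    res = optimize.minimize(
        _objective, best.x, args=args, method="Nelder-Mead", options=opts
    )
    if res.fun < best.fun:
        best = res
    params, per_cond = _unpack(best.x, spec, cond_levels, base)
    k = spec.n_params(len(cond_levels))
    gsq = float(best.fun)
    observed = {(c["condition"], c["signal"]): c["counts"] for c in cells}
    expected = {}
    for cell in cells:
        p = replace(params, **per_cond.get(cell["condition"], {}))
        drift = p.drift_for(cell["signal"])
        if use_sim:
            props = expected_props_simulated(cell, p, drift, n_sim=n_sim, seed=sim_seed)
        else:
            props = expected_props_analytic(cell, p, drift)
        expected[(cell["condition"], cell["signal"])] = props * cell["counts"].sum()
    return FitResult(
        params=params,
        per_condition=per_cond,
        gsq=gsq,
        n_trials=n_total,
        k_params=k,
        bic=gsq + k * np.log(n_total),
        converged=bool(best.success),
        observed_bins=observed,
        expected_bins=expected,
    )


def bic_compare(fits: Mapping[str, FitResult]):
    """Rank fitted models by BIC (lowest wins); deltas < 2 flagged as ties."""
    ns = {f.n_trials for f in fits.values()}
    if len(ns) > 1:
        raise ValueError("BIC comparison requires fits on identical data")
    order = sorted(fits.items(), key=lambda kv: kv[1].bic)
    best_bic = order[0][1].bic
    return [
        {"model": name, "bic": f.bic, "delta": f.bic - best_bic,
         "tie": 0.0 < f.bic - best_bic < 2.0}
        for name, f in order
    ]


def predict_behavior_metrics(
    params: DDMParams,
    per_condition: Mapping | None = None,
    signal_frac: float = 0.5,
    n_trials: int = 100_000,
    seed: int = 0,
):
    """Forward-simulate a fitted model and summarise per-condition behavior
    (RT, d-prime, criterion) with signal/noise composition matched to the
    design, mirroring the model-prediction overlays of the empirical plots."""
    from . import sdt

    per_condition = per_condition or {0: {}}
    rng = np.random.default_rng(seed)
    out = {}
    for cond, overrides in per_condition.items():
        p = replace(params, **overrides)
        n_sig = int(round(n_trials * signal_frac))
        signal = np.zeros(n_trials, dtype=bool)
        signal[:n_sig] = True
        choices, rts = simulate_ddm(p, signal=signal, seed=int(rng.integers(2**31 - 1)))
        yes = choices == 1
        n_hit = int(np.sum(yes & signal))
        n_miss = int(np.sum(~yes & signal))
        n_fa = int(np.sum(yes & ~signal))
        n_cr = int(np.sum(~yes & ~signal))
        m = sdt.sdt_d_prime_criterion(n_hit, n_miss, n_fa, n_cr)
        out[cond] = {
            "rt": float(np.nanmean(rts[yes])),
            "d_prime": m.d_prime,
            "criterion": m.criterion,
        }
    return out
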