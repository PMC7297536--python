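"""Synthetic behavioral datasets and pupil traces with known ground truth.

Emulates the study designs this package analyses:

* go/no-go mini-blocks of 2-7 one-second trials, signal always on the final
  trial, with the probability of the signal declining linearly over
  within-block position and loudness levels balanced across the session;
* yes/no (forced-choice) sessions with stratified signal probability
  (0.5, or 0.3/0.7 for biased environments) and a 50/50 old/new
  recognition variant;
* a latent per-trial arousal variable coupled to the drift bias of the
  diffusion process that generates choices and RTs;
* pupil traces built from slow baseline drift, arousal-scaled impulse
  responses at trial onsets, motor transients at responses, blink gaps with
  post-gap dilation, and Gaussian noise.

The arousal -> bias coupling is multiplicative suppression,

    v_bias(trial) = bias_base * (1 - gamma * arousal_rank01),

so biases of either sign shrink toward zero as arousal grows -- the pattern
an additive (purely liberalizing) coupling cannot produce.  The coupling law
is configurable through ArousalCouplingSpec.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .ddm import DDMParams, simulate_ddm
from .preproc import PupilTrace


@dataclass
class TaskSpec:
    task_kind: str = "gonogo"  # gonogo | yesno | recognition
    n_subjects: int = 1
    trials_per_subject: int = 660
    signal_prob: float = 0.5
    loudness_levels: tuple = (-40.0, -30.0, -20.0, -10.0, -5.0)
    miniblock_range: tuple = (2, 7)
    trial_dur_s: float = 1.0
    iti_s: float = 0.5
    sampling_rate_hz: float = 1000.0
    block_size: int = 120  # stratification block for yes/no designs

    def validate(self) -> None:
        lo, hi = self.miniblock_range
        if lo < 2 or hi > 7 or lo > hi:
            raise ValueError("miniblock_range must satisfy 2 <= lo <= hi <= 7")
        if not 0 < self.signal_prob < 1:
            raise ValueError("signal_prob must lie in (0, 1)")
        if len(self.loudness_levels) == 0:
            raise ValueError("need at least one loudness level")


#: mouse sessions: 6 loudness levels, 2469-3479 trials, early scalar window
MOUSE_GONOGO = TaskSpec(
    task_kind="gonogo",
    trials_per_subject=2974,
    loudness_levels=(-30.0, -24.0, -18.0, -12.0, -6.0, 0.0),
)
HUMAN_GONOGO = TaskSpec(task_kind="gonogo", trials_per_subject=660)
HUMAN_YESNO = TaskSpec(task_kind="yesno", trials_per_subject=1320, loudness_levels=(-20.0,))
HUMAN_YESNO_BIASED = TaskSpec(
    task_kind="yesno", trials_per_subject=960, signal_prob=0.3, loudness_levels=(-20.0,)
)
RECOGNITION = TaskSpec(
    task_kind="recognition", trials_per_subject=300, signal_prob=0.5, loudness_levels=(0.0,)
)


@dataclass
class ArousalCouplingSpec:
    arousal_sigma: float = 0.5  # lognormal shape; unit median
    bias_base: float = -0.5  # conservative by default (toward the no bound)
    coupling_gamma: float = 1.0
    max_flip_frac: float = 0.25  # cap on sign-flipped bias magnitude
    irf_tmax_s: float = 0.93
    irf_shape: float = 10.1
    arousal_gain: float = 1.0  # trace units per unit arousal
    motor_transient_amp: float = 0.5
    blink_rate_hz: float = 0.1
    blink_dilation_amp: float = 0.3
    noise_sd: float = 0.05
    baseline_drift_sd: float = 0.5
    baseline_mean_au: float = 1000.0

    def validate(self) -> None:
        if self.coupling_gamma < 0:
            raise ValueError("coupling_gamma must be >= 0")


@dataclass
class GroundTruth:
    arousal: np.ndarray
    effective_v_bias: np.ndarray
    params: DDMParams
    onset_t_s: np.ndarray
    response_t_s: np.ndarray
    blink_t_s: np.ndarray = field(default_factory=lambda: np.array([]))


# ---------------------------------------------------------------------------
# designs

# linearly decreasing probability of the signal over block lengths 2..7
_BLOCK_LENGTHS = np.arange(2, 8)


def _block_length_pmf(lo: int, hi: int) -> tuple[np.ndarray, np.ndarray]:
    lengths = np.arange(lo, hi + 1)
    w = (hi + 1.0) - lengths  # linear decline of P(signal at position k)
    return lengths, w / w.sum()


def make_gonogo_design(
    spec: TaskSpec, seed: int, n_miniblocks: int | None = None
) -> pd.DataFrame:
    """Mini-block go/no-go design: signal on the final trial of each block,
    block lengths drawn so the marginal signal probability declines linearly
    with within-block position, loudness balanced across blocks, first trial
    of each block flagged as the (excluded) cue trial.

    By default blocks are drawn until the session holds exactly
    ``trials_per_subject`` trials (the final lengths are constrained to land
    on the total); pass ``n_miniblocks`` to fix the block count instead.
    """
    spec.validate()
    if spec.task_kind != "gonogo":
        raise ValueError("task_kind must be gonogo")
    rng = np.random.default_rng(seed)
    lo, hi = spec.miniblock_range
    lengths_all, pmf = _block_length_pmf(lo, hi)
    lengths = []
    if n_miniblocks is not None:
        lengths = list(rng.choice(lengths_all, size=n_miniblocks, p=pmf))
    else:
        remaining = spec.trials_per_subject
        while remaining > 0:
            allowed = [
                int(k) for k in lengths_all if k == remaining or remaining - k >= lo
            ]
            p = np.array([pmf[k - lo] for k in allowed])
            k = int(rng.choice(allowed, p=p / p.sum()))
            lengths.append(k)
            remaining -= k
    n_blocks = len(lengths)
    levels = list(spec.loudness_levels)
    reps = n_blocks // len(levels)
    rem = n_blocks - reps * len(levels)
    loud = np.array(levels * reps + list(rng.choice(levels, rem, replace=False)))
    rng.shuffle(loud)
    rows = []
    for b, (L, lv) in enumerate(zip(lengths, loud)):
        for j in range(L):
            rows.append(
                {
                    "miniblock": b,
                    "trial_idx": j + 1,
                    "is_cue_trial": j == 0,
                    "signal_present": int(j == L - 1),
                    "loudness_db": lv if j == L - 1 else np.nan,
                }
            )
    df = pd.DataFrame(rows)
    df.insert(0, "trial", np.arange(len(df)))
    return df


def make_yesno_design(spec: TaskSpec, seed: int) -> pd.DataFrame:
    """Yes/no (or old/new recognition) design with exact stratified signal
    counts per block and a fixed loudness per subject."""
    spec.validate()
    if spec.task_kind not in ("yesno", "recognition"):
        raise ValueError("task_kind must be yesno or recognition")
    rng = np.random.default_rng(seed)
    p_sig = 0.5 if spec.task_kind == "recognition" else spec.signal_prob
    n = spec.trials_per_subject
    bs = min(spec.block_size, n)
    flags = []
    done = 0
    while done < n:
        m = min(bs, n - done)
        k = int(round(p_sig * m))
        block = np.zeros(m, dtype=int)
        block[:k] = 1
        rng.shuffle(block)
        flags.append(block)
        done += m
    flags = np.concatenate(flags)
    df = pd.DataFrame(
        {
            "trial": np.arange(n),
            "miniblock": np.arange(n) // bs,
            "trial_idx": np.arange(n) % bs + 1,
            "is_cue_trial": False,
            "signal_present": flags,
            "loudness_db": np.where(flags == 1, spec.loudness_levels[0], np.nan),
        }
    )
    return df


def make_design(spec: TaskSpec, seed: int) -> pd.DataFrame:
    if spec.task_kind == "gonogo":
        return make_gonogo_design(spec, seed)
    return make_yesno_design(spec, seed)


# ---------------------------------------------------------------------------
# behavior


def _rank01(x: np.ndarray) -> np.ndarray:
    order = np.argsort(np.argsort(x, kind="stable"), kind="stable")
    if x.size == 1:
        return np.zeros(1)
    return order / (x.size - 1.0)


def effective_drift_bias(
    arousal: np.ndarray, coupling: ArousalCouplingSpec
) -> np.ndarray:
    """Multiplicative suppression of the baseline drift bias by arousal.

    Arousal is rank-normalised to [0, 1]; suppression beyond the configured
    sign-flip cap is clamped with a warning.
    """
    coupling.validate()
    a01 = _rank01(arousal)
    factor = 1.0 - coupling.coupling_gamma * a01
    floor = -coupling.max_flip_frac
    if np.any(factor < floor):
        warnings.warn("coupling flips bias beyond the configured cap; clamping")
        factor = np.maximum(factor, floor)
    return coupling.bias_base * factor


def simulate_subject_behavior(
    design: pd.DataFrame,
    params: DDMParams,
    coupling: ArousalCouplingSpec,
    seed: int,
    task_kind: str = "gonogo",
    trial_dur_s: float = 1.0,
    iti_s: float = 0.5,
    dt: float = 0.001,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw latent arousal, couple it into the drift bias, and run the
    diffusion simulator trial by trial.

    go/no-go trials that do not reach the upper bound within the trial
    duration are no-go choices with absent RT.
    """
    rng = np.random.default_rng(seed)
    n = len(design)
    arousal = np.exp(coupling.arousal_sigma * rng.standard_normal(n))
    v_bias_t = effective_drift_bias(arousal, coupling)
    sig = design["signal_present"].to_numpy().astype(bool)
    loud = design["loudness_db"].to_numpy()
    from dataclasses import replace as _replace

    p0 = _replace(params, v_bias=0.0)
    base_drift = np.array(
        [
            p0.drift_for(s, l if np.isfinite(l) else None)
            for s, l in zip(sig, loud)
        ]
    )
    drifts = base_drift + v_bias_t
    t_max = trial_dur_s if task_kind == "gonogo" else 10.0
    sim_params = DDMParams(
        v=1.0, v_bias=0.0, z_rel=params.z_rel, a=params.a, t0=params.t0,
        sv=params.sv, s=params.s, tau_urgency=params.tau_urgency,
    )
    choices, rts = simulate_ddm(
        sim_params, drifts=drifts, seed=int(rng.integers(2**31 - 1)), dt=dt,
        t_max=t_max,
    )
    if task_kind == "gonogo":
        go = choices == 1
        choice = go.astype(float)
        rt = np.where(go, rts, np.nan)
    else:
        choice = np.where(choices >= 0, choices, np.nan).astype(float)
        rt = rts
    onset = np.arange(n) * (trial_dur_s + iti_s)
    resp = np.where(np.isfinite(rt), onset + rt, np.nan)
    table = design.copy()
    table["choice"] = choice
    table["rt_s"] = rt
    table["correct"] = (choice == sig.astype(float)).astype(int)
    table["onset_t_s"] = onset
    truth = GroundTruth(
        arousal=arousal,
        effective_v_bias=v_bias_t,
        params=params,
        onset_t_s=onset,
        response_t_s=resp,
    )
    return table, truth


# ---------------------------------------------------------------------------
# pupil traces


def pupil_irf(t: np.ndarray, t_max: float = 0.93, shape: float = 10.1) -> np.ndarray:
    """Gamma-family pupil impulse response, unit peak at t = t_max."""
    t = np.asarray(t, dtype=float)
    h = np.zeros_like(t)
    pos = t > 0
    tp = t[pos] / t_max
    h[pos] = tp**shape * np.exp(-shape * (tp - 1.0))
    return h


def synthesize_pupil_traces(
    design: pd.DataFrame,
    truth: GroundTruth,
    coupling: ArousalCouplingSpec,
    seed: int,
    sampling_rate_hz: float = 1000.0,
    trial_dur_s: float = 1.0,
    iti_s: float = 0.5,
    tail_s: float = 6.0,
) -> PupilTrace:
    """Build a session-long pupil trace for one subject.

    trace = baseline mean + slow drift + sum_t arousal_t * IRF(t - onset_t)
          + motor_amp * IRF(t - response_t) (responses only)
          + blink-evoked dilations + Gaussian noise,
    with blink gaps (100-400 ms) masked as missing.  Overlapping gaps merge.
    """
    rng = np.random.default_rng(seed)
    fs = sampling_rate_hz
    dur = len(design) * (trial_dur_s + iti_s) + tail_s
    n = int(round(dur * fs))
    kernel = pupil_irf(np.arange(0, 4.0, 1.0 / fs), coupling.irf_tmax_s, coupling.irf_shape)

    def impulses(times, amps):
        x = np.zeros(n)
        for t, a in zip(times, amps):
            i = int(round(t * fs))
            if 0 <= i < n:
                x[i] += a
        return np.convolve(x, kernel)[:n]

    trace = np.full(n, coupling.baseline_mean_au, dtype=float)
    # slow baseline drift: linear interpolation between coarse random knots
    if coupling.baseline_drift_sd > 0:
        knots_t = np.arange(0, dur + 20.0, 20.0)
        knots_v = rng.normal(0, coupling.baseline_drift_sd, knots_t.size)
        trace += np.interp(np.arange(n) / fs, knots_t, knots_v)
    trace += coupling.arousal_gain * impulses(truth.onset_t_s, truth.arousal)
    if coupling.motor_transient_amp > 0:
        resp = truth.response_t_s[np.isfinite(truth.response_t_s)]
        trace += impulses(resp, np.full(resp.size, coupling.motor_transient_amp))
    mask = np.zeros(n, dtype=bool)
    blink_times = np.array([])
    if coupling.blink_rate_hz > 0:
        n_blinks = rng.poisson(coupling.blink_rate_hz * dur)
        blink_times = np.sort(rng.uniform(0, dur - 0.5, n_blinks))
        gap_ends = []
        for bt in blink_times:
            gap = rng.uniform(0.1, 0.4)
            i0, i1 = int(bt * fs), min(int((bt + gap) * fs), n)
            mask[i0:i1] = True
            gap_ends.append(bt + gap)
        if coupling.blink_dilation_amp > 0 and gap_ends:
            trace += impulses(
                np.array(gap_ends),
                np.full(len(gap_ends), coupling.blink_dilation_amp),
            )
    if coupling.noise_sd > 0:
        trace += rng.normal(0, coupling.noise_sd, n)
    events = [("trial_onset", float(t)) for t in truth.onset_t_s]
    events += [
        ("response", float(t)) for t in truth.response_t_s if np.isfinite(t)
    ]
    events += [("blink", float(t)) for t in blink_times]
    truth.blink_t_s = blink_times
    return PupilTrace(trace, fs, mask, events)


# ---------------------------------------------------------------------------
# dataset assembly


def generate_dataset(
    spec: TaskSpec,
    params: DDMParams,
    coupling: ArousalCouplingSpec,
    seed: int,
    out_dir: str | Path | None = None,
    traces: bool = True,
):
    """Generate a full multi-subject dataset (trial tables, traces, ground
    truth).  Deterministic for a given seed; optionally written to disk as
    tab-delimited tables, two-column trace files and a JSON sidecar."""
    ss = np.random.SeedSequence(seed)
    subject_seeds = ss.spawn(spec.n_subjects)
    tables, truths, trace_list = [], {}, {}
    for s, sub_ss in enumerate(subject_seeds):
        s_rng = np.random.default_rng(sub_ss)
        seeds = s_rng.integers(0, 2**31 - 1, size=3)
        design = make_design(spec, int(seeds[0]))
        table, truth = simulate_subject_behavior(
            design, params, coupling, int(seeds[1]), task_kind=spec.task_kind,
            trial_dur_s=spec.trial_dur_s, iti_s=spec.iti_s,
        )
        table.insert(0, "subject_id", f"s{s:02d}")
        table.insert(1, "session", 1)
        table.insert(2, "task", spec.task_kind)
        tables.append(table)
        truths[f"s{s:02d}"] = truth
        if traces:
            trace_list[f"s{s:02d}"] = synthesize_pupil_traces(
                design, truth, coupling, int(seeds[2]),
                sampling_rate_hz=spec.sampling_rate_hz,
                trial_dur_s=spec.trial_dur_s, iti_s=spec.iti_s,
            )
    trials = pd.concat(tables, ignore_index=True)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        trials.to_csv(out / "trials.tsv", sep="\t", index=False)
        gt = {
            sid: {
                "arousal": t.arousal.tolist(),
                "effective_v_bias": t.effective_v_bias.tolist(),
                "params": {
                    k: (v if not isinstance(v, dict) else v)
                    for k, v in asdict(t.params).items()
                },
            }
            for sid, t in truths.items()
        }
        (out / "ground_truth.json").write_text(json.dumps(gt))
        for sid, tr in trace_list.items():
            df = pd.DataFrame(
                {
                    "time_s": tr.time,
                    "pupil_au": tr.samples,
                    "missing": tr.missing_mask.astype(int),
                }
            )
            df.to_csv(out / f"trace_{sid}.tsv", sep="\t", index=False)
            ev = pd.DataFrame(tr.events, columns=["kind", "time_s"])
            ev.to_csv(out / f"events_{sid}.tsv", sep="\t", index=False)
    return trials, truths, trace_list
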