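"""Pupil-trace preprocessing: from raw diameter series to per-trial
phasic-arousal scalars and equal-population arousal bins.

The pipeline follows standard pupillometry practice for fast-paced
detection tasks: (i) linear interpolation across blink gaps (each gap padded
by 150 ms on both sides), (ii) zero-phase third-order Butterworth low-pass
at 6 Hz, (iii) optional FIR deconvolution and regression-based removal of
blink/saccade-evoked dilations, (iv) conversion to percent signal change
about the session mean, (v) anti-aliased down-sampling to 50 Hz.  Phasic
arousal on each trial is the 95th percentile of the low-passed (2 Hz)
first derivative inside a configured window -- early post-stimulus for
go/no-go designs (before the motor transient can contaminate it), pre-choice
for yes/no designs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import sparse
from scipy.sparse.linalg import lsqr


@dataclass
class PupilTrace:
    """Uniformly sampled pupil series with missing mask and events.

    events: list of (kind, time_s) with kind in
    {trial_onset, response, blink, saccade}.
    """

    samples: np.ndarray
    rate_hz: float
    missing_mask: np.ndarray | None = None
    events: list = field(default_factory=list)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.missing_mask is None:
            self.missing_mask = np.zeros(self.samples.size, dtype=bool)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.missing_mask.size != self.samples.size:
            raise ValueError("mask and samples must have equal length")

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.rate_hz

    def event_times(self, kind: str) -> np.ndarray:
        return np.array([t for k, t in self.events if k == kind], dtype=float)


@dataclass
class PreprocConfig:
    interp_pad_s: float = 0.15
    lowpass_cut_hz: float = 6.0
    deriv_lowpass_cut_hz: float = 2.0
    target_rate_hz: float = 50.0
    deconv_epoch_s: float = 6.0
    deconv_bin_s: float = 0.1
    deconvolve: bool = True
    # (reference, start_s, end_s): offsets relative to the reference event
    scalar_window: tuple = ("stimulus", 0.23, 0.50)
    rt_cutoff_s: float = 0.55
    n_bins: int = 5
    baseline_window_s: float = 0.5
    max_missing_frac: float = 0.4

    def validate(self, rate_hz: float) -> None:
        if self.scalar_window[1] >= self.scalar_window[2]:
            raise ValueError("scalar window must be well-ordered")
        nyq = min(rate_hz, self.target_rate_hz) / 2.0
        if self.lowpass_cut_hz >= rate_hz / 2.0 or self.deriv_lowpass_cut_hz >= nyq:
            raise ValueError("filter cutoffs must lie below Nyquist at every stage")


MOUSE_GONOGO_WINDOW = ("stimulus", 0.04, 0.23)
HUMAN_GONOGO_WINDOW = ("stimulus", 0.23, 0.50)
YESNO_CHOICE_WINDOW = ("choice", -0.5, 0.0)
MOUSE_RT_CUTOFF = 0.28
HUMAN_RT_CUTOFF = 0.55


def _find_gaps(mask: np.ndarray):
    """(start, stop) index pairs (half-open) of True runs in the mask."""
    d = np.diff(mask.astype(np.int8), prepend=0, append=0)
    starts = np.nonzero(d == 1)[0]
    stops = np.nonzero(d == -1)[0]
    return list(zip(starts, stops))


def clean_trace(trace: PupilTrace, config: PreprocConfig) -> PupilTrace:
    """Interpolate missing data (gaps padded on both sides) and low-pass.

    Gaps at the trace edge are held at the nearest valid value.  A fully
    missing trace is an error; traces missing more than ``max_missing_frac``
    are processed with a warning.
    """
    config.validate(trace.rate_hz)
    x = trace.samples.copy()
    mask = trace.missing_mask.copy()
    n = x.size
    if mask.all():
        raise ValueError("trace has no valid samples")
    if mask.mean() > config.max_missing_frac:
        warnings.warn(
            f"{mask.mean():.0%} of samples missing; session flagged as low quality"
        )
    pad = int(round(config.interp_pad_s * trace.rate_hz))
    # extend each gap by the pad on both sides, then merge via the mask
    ext = mask.copy()
    for s, e in _find_gaps(mask):
        ext[max(0, s - pad) : min(n, e + pad)] = True
    if ext.all():
        raise ValueError("padded gaps cover the whole trace")
    idx = np.arange(n)
    x[ext] = np.interp(idx[ext], idx[~ext], x[~ext])  # edge gaps -> held value
    b, a = sps.butter(3, config.lowpass_cut_hz / (trace.rate_hz / 2.0), "low")
    x = sps.filtfilt(b, a, x)
    return PupilTrace(x, trace.rate_hz, np.zeros(n, dtype=bool), list(trace.events))


def deconvolve_artifacts(trace: PupilTrace, config: PreprocConfig) -> PupilTrace:
    """Estimate and regress out blink- and saccade-evoked pupil responses.

    The event-evoked responses are estimated as finite impulse responses on
    a boxcar basis of width ``deconv_bin_s`` spanning ``deconv_epoch_s``
    after each event (least squares on the lagged indicator design), then
    the fitted event-locked contribution is subtracted.  With no events the
    trace is returned unchanged; with fewer than two events of every kind
    the step warns and skips.
    """
    if not config.deconvolve:
        return trace
    kinds = [k for k in ("blink", "saccade") if trace.event_times(k).size > 0]
    if not kinds:
        return trace
    if all(trace.event_times(k).size < 2 for k in kinds):
        warnings.warn("too few blink/saccade events for deconvolution; skipping")
        return trace
    n = trace.samples.size
    rate = trace.rate_hz
    bin_samp = max(1, int(round(config.deconv_bin_s * rate)))
    n_lags = int(np.ceil(config.deconv_epoch_s * rate / bin_samp))
    cols, rows, vals = [], [], []
    col0 = 0
    for kind in kinds:
        ev_idx = np.round(trace.event_times(kind) * rate).astype(int)
        for j in range(n_lags):
            for e in ev_idx:
                s = e + j * bin_samp
                t = min(s + bin_samp, n)
                if s >= n:
                    continue
                r = np.arange(s, t)
                rows.append(r)
                cols.append(np.full(r.size, col0 + j))
                vals.append(np.ones(r.size))
        col0 += n_lags
    # intercept column so the FIR is not offset by the baseline level
    rows.append(np.arange(n))
    cols.append(np.full(n, col0))
    vals.append(np.ones(n))
    X = sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, col0 + 1),
    )
    beta = lsqr(X, trace.samples, atol=1e-12, btol=1e-12, iter_lim=2000)[0]
    cleaned = trace.samples - X[:, :col0] @ beta[:col0]
    out = replace(trace, samples=cleaned)
    out.fir_estimates = {
        kind: beta[i * n_lags : (i + 1) * n_lags] for i, kind in enumerate(kinds)
    }
    return out


def normalize_downsample(trace: PupilTrace, config: PreprocConfig) -> PupilTrace:
    """Percent signal change about the session mean, then decimate."""
    mu = trace.samples.mean()
    if mu <= 0:
        raise ValueError("session mean must be positive for percent-change units")
    x = 100.0 * (trace.samples - mu) / mu
    q = trace.rate_hz / config.target_rate_hz
    if q < 1:
        raise ValueError("target rate above native rate")
    if abs(q - round(q)) < 1e-9:
        q = int(round(q))
        if q > 1:
            x = sps.decimate(x, q, ftype="iir", zero_phase=True)
    else:
        from fractions import Fraction

        frac = Fraction(config.target_rate_hz / trace.rate_hz).limit_denominator(1000)
        x = sps.resample_poly(x, frac.numerator, frac.denominator)
    return PupilTrace(x, config.target_rate_hz, None, list(trace.events))


def compute_derivative(trace: PupilTrace, config: PreprocConfig) -> PupilTrace:
    """Adjacent-sample difference scaled to %/s, low-passed at 2 Hz.

    The last sample is repeated so the output aligns with the input length.
    """
    if trace.samples.size < 15:
        raise ValueError("trace too short for derivative filtering")
    d = np.diff(trace.samples) * trace.rate_hz
    d = np.concatenate([d, d[-1:]])
    b, a = sps.butter(3, config.deriv_lowpass_cut_hz / (trace.rate_hz / 2.0), "low")
    d = sps.filtfilt(b, a, d)
    return PupilTrace(d, trace.rate_hz, None, list(trace.events))


def extract_phasic_scalar(
    deriv_trace: PupilTrace,
    norm_trace: PupilTrace,
    trials: pd.DataFrame,
    config: PreprocConfig,
) -> pd.DataFrame:
    """Per-trial phasic scalar and pre-trial baseline.

    scalar = 95th percentile of the derivative inside the configured window
    (anchored at stimulus onset or at the choice); baseline = mean of the
    normalized trace in the ``baseline_window_s`` before trial onset.
    Trials whose window has fewer than two samples are flagged excluded.
    """
    ref, w0, w1 = config.scalar_window
    rate = deriv_trace.rate_hz
    out = trials.copy()
    scalars = np.full(len(out), np.nan)
    baselines = np.full(len(out), np.nan)
    ok = np.ones(len(out), dtype=bool)
    n = deriv_trace.samples.size
    onsets = out["onset_t_s"].to_numpy(dtype=float)
    rts = out["rt_s"].to_numpy(dtype=float) if "rt_s" in out else np.full(len(out), np.nan)
    for i in range(len(out)):
        if ref == "choice":
            if not np.isfinite(rts[i]):
                ok[i] = False
                continue
            anchor = onsets[i] + rts[i]
        else:
            anchor = onsets[i]
        s = int(np.round((anchor + w0) * rate))
        e = int(np.round((anchor + w1) * rate))
        if s < 0 or e > n or e - s < 2:
            ok[i] = False
            continue
        scalars[i] = np.percentile(deriv_trace.samples[s:e], 95)
        b0 = int(np.round((onsets[i] - config.baseline_window_s) * norm_trace.rate_hz))
        b1 = int(np.round(onsets[i] * norm_trace.rate_hz))
        if b0 >= 0 and b1 > b0:
            baselines[i] = norm_trace.samples[b0:b1].mean()
    out["phasic_scalar"] = scalars
    out["baseline_pupil"] = baselines
    out["included"] = ok
    return out


def exclude_fast_trials(trials: pd.DataFrame, config: PreprocConfig) -> pd.DataFrame:
    """Drop go-choice trials faster than the RT cutoff and cue trials.

    No-go trials (absent RT) are always retained: the exclusion exists to
    keep motor transients out of the scalar window, which only responses
    can produce.
    """
    out = trials.copy()
    rt = out["rt_s"].to_numpy(dtype=float) if "rt_s" in out else np.full(len(out), np.nan)
    fast = np.isfinite(rt) & (rt < config.rt_cutoff_s)
    keep = ~fast
    if "is_cue_trial" in out:
        keep &= ~out["is_cue_trial"].astype(bool).to_numpy()
    return out.loc[keep].reset_index(drop=True)


def assign_pupil_bins(
    trials: pd.DataFrame,
    config: PreprocConfig,
    stratify_by: str | None = None,
) -> pd.DataFrame:
    """Equal-population arousal bins, optionally within strata.

    Within each stratum (e.g. loudness level) the included trials are ranked
    by phasic scalar (stable order on ties) and split into ``n_bins``
    contiguous groups whose sizes differ by at most one.
    """
    out = trials.copy()
    out["pupil_bin"] = -1
    inc = out["included"] if "included" in out else pd.Series(True, index=out.index)
    idx_all = out.index[inc & out["phasic_scalar"].notna()]
    if stratify_by is None:
        groups = [idx_all]
    else:
        groups = [
            idx_all[out.loc[idx_all, stratify_by] == lev]
            for lev in pd.unique(out.loc[idx_all, stratify_by])
        ]
    for g in groups:
        if len(g) == 0:
            continue
        if len(g) < config.n_bins:
            warnings.warn("stratum smaller than number of bins; bins of size >= 1")
        order = np.argsort(out.loc[g, "phasic_scalar"].to_numpy(), kind="stable")
        chunks = np.array_split(np.asarray(g)[order], min(config.n_bins, len(g)))
        for b, chunk in enumerate(chunks):
            out.loc[chunk, "pupil_bin"] = b
    return out


def preprocess_session(
    trace: PupilTrace,
    trials: pd.DataFrame,
    config: PreprocConfig,
    stratify_by: str | None = None,
) -> pd.DataFrame:
    """Full per-session pipeline: clean, deconvolve, normalize, derivative,
    scalar extraction, fast-trial exclusion, binning."""
    t = clean_trace(trace, config)
    t = deconvolve_artifacts(t, config)
    norm = normalize_downsample(t, config)
    deriv = compute_derivative(norm, config)
    aug = extract_phasic_scalar(deriv, norm, trials, config)
    aug = exclude_fast_trials(aug, config)
    return assign_pupil_bins(aug, config, stratify_by=stratify_by)
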