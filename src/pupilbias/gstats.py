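"""Group-level inference.

* sequential polynomial mixed-model selection: is a behavioral metric
  constant, linear, or quadratic in arousal bin?  Nested candidates
  (constant / + linear bin term / + quadratic bin term, with signal loudness
  as a covariate where the design has one) are fitted by maximum likelihood
  with subject-level random effects, compared by BIC, and the winner is
  refitted by restricted maximum likelihood;
* cluster-corrected one-sample tests on subject x time matrices
  (sign-flipping permutation null on the cluster-mass statistic);
* paired t-tests and Pearson correlations with percentile-bootstrap
  confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats


@dataclass
class SequentialModelResult:
    selected_order: str  # constant | linear | quadratic
    coefficients: dict
    bse: dict
    bic: dict
    result: object  # statsmodels results object of the REML-refitted winner


@dataclass
class ClusterTestResult:
    clusters: list  # (start_s, end_s) of significant clusters
    masses: list
    p_values: list
    alpha: float
    t_values: np.ndarray


def _mixedlm_bic(res) -> float:
    # -2 ln L + k ln(n); k counts fixed effects + RE (co)variances + scale
    k = res.k_fe + res.k_re2 + 1
    return float(-2.0 * res.llf + k * np.log(res.nobs))


def fit_sequential_polynomial(
    table: pd.DataFrame,
    y: str = "y",
    subject: str = "subject",
    pupil: str = "P",
    loudness: str | None = None,
    re_on_slopes: bool = True,
) -> SequentialModelResult:
    """Select among constant / linear / quadratic dependence on pupil bin.

    ``table`` holds one row per subject x (loudness x) bin with the metric
    ``y``.  Candidates are fitted by ML with subject random intercepts and,
    where estimable, random slopes on the predictors; the model with lowest
    BIC wins in a serial comparison (a higher order is adopted only when it
    improves on the current winner), then is refitted by REML.  Degenerate
    random-effect fits fall back to random intercepts only with a warning.
    """
    import statsmodels.formula.api as smf

    df = table.copy()
    if df[subject].nunique() < 2 or df[pupil].nunique() < 2:
        raise ValueError("need at least two subjects and two pupil bins")
    df["_P"] = df[pupil].astype(float)
    df["_P2"] = df["_P"] ** 2
    base_terms = [loudness] if loudness else []
    formulas = {
        "constant": "{y} ~ 1".format(y=y)
        + ("".join(f" + {t}" for t in base_terms)),
        "linear": "{y} ~ 1".format(y=y)
        + ("".join(f" + {t}" for t in base_terms))
        + " + _P",
        "quadratic": "{y} ~ 1".format(y=y)
        + ("".join(f" + {t}" for t in base_terms))
        + " + _P + _P2",
    }
    # one common random-effects structure for every candidate, so BIC
    # differences reflect the fixed-effect polynomial order alone; the
    # quadratic term enters fixed effects only
    common_re = "~_P" if re_on_slopes else "~1"
    if loudness and re_on_slopes:
        common_re = f"~{loudness}+_P"
    re_formulas = {"constant": common_re, "linear": common_re, "quadratic": common_re}

    def _fit(order, reml):
        re_f = re_formulas[order]
        for attempt_re in (re_f, "~1"):
            for method in (None, "powell"):
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        m = smf.mixedlm(
                            formulas[order], df, groups=df[subject], re_formula=attempt_re
                        )
                        r = m.fit(reml=reml) if method is None else m.fit(
                            reml=reml, method=method, maxiter=500
                        )
                    if np.all(np.isfinite(r.params)):
                        if attempt_re == "~1" and re_f != "~1":
                            warnings.warn(
                                f"random-effects structure degenerate for {order}; "
                                "falling back to random intercepts"
                            )
                        return r
                except Exception:  # noqa: BLE001 - fall through the ladder
                    continue
        raise ValueError(f"mixed model for {order} failed to fit")

    bics = {}
    fits = {}
    for order in ("constant", "linear", "quadratic"):
        fits[order] = _fit(order, reml=False)
        bics[order] = _mixedlm_bic(fits[order])
    # serial hierarchical selection: each higher order is adopted only if it
    # improves on the current winner
    selected = "constant"
    if bics["linear"] < bics[selected]:
        selected = "linear"
    if bics["quadratic"] < bics[selected]:
        selected = "quadratic"
    final = _fit(selected, reml=True)
    return SequentialModelResult(
        selected_order=selected,
        coefficients=dict(final.fe_params),
        bse=dict(final.bse_fe),
        bic=bics,
        result=final,
    )


def _cluster_masses(t_vals: np.ndarray, thresh: float):
    """Clusters of contiguous supra-threshold |t| with their signed mass."""
    supra = np.abs(t_vals) > thresh
    clusters, masses = [], []
    i = 0
    n = t_vals.size
    while i < n:
        if supra[i]:
            j = i
            while j < n and supra[j] and np.sign(t_vals[j]) == np.sign(t_vals[i]):
                j += 1
            clusters.append((i, j))
            masses.append(float(np.sum(t_vals[i:j])))
            i = j
        else:
            i += 1
    return clusters, masses


def cluster_permutation_timecourse(
    data: np.ndarray,
    rate_hz: float = 50.0,
    alpha: float = 0.05,
    n_perm: int = 10_000,
    seed: int = 0,
) -> ClusterTestResult:
    """One-sample cluster-corrected test on a subject x time matrix.

    Pointwise one-sample t-values are thresholded at the two-sided alpha
    quantile; contiguous supra-threshold samples form clusters scored by
    their t-mass, and the null distribution of the maximum |mass| is built
    by sign-flipping subjects (n_perm permutations).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 5:
        raise ValueError("need a subject x time matrix with >= 5 subjects")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    n_subj, n_time = data.shape
    thresh = sstats.t.ppf(1 - alpha / 2.0, df=n_subj - 1)

    def tvals(x):
        m = x.mean(axis=0)
        se = x.std(axis=0, ddof=1) / np.sqrt(n_subj)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, m / se, 0.0)
        return t

    t_obs = tvals(data)
    clusters, masses = _cluster_masses(t_obs, thresh)
    rng = np.random.default_rng(seed)
    null_max = np.zeros(n_perm)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_subj))
    for p in range(n_perm):
        t_p = tvals(data * signs[p][:, None])
        _, m_p = _cluster_masses(t_p, thresh)
        null_max[p] = max((abs(m) for m in m_p), default=0.0)
    out_clusters, out_masses, out_p = [], [], []
    for (i, j), m in zip(clusters, masses):
        p_val = float((np.sum(null_max >= abs(m)) + 1) / (n_perm + 1))
        if p_val < alpha:
            out_clusters.append((i / rate_hz, j / rate_hz))
            out_masses.append(m)
            out_p.append(p_val)
    return ClusterTestResult(out_clusters, out_masses, out_p, alpha, t_obs)


def association_tests(
    x, y, kind: str = "pearson_bootstrap", ci_level: float = 0.60,
    n_boot: int = 5000, seed: int = 0,
) -> dict:
    """Paired t-test or Pearson correlation with a percentile-bootstrap CI.

    The default 60% CI level matches the error bars used for
    individual-differences scatter plots.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need n >= 3")
    if kind == "paired_t":
        d = x - y
        if np.allclose(d.std(ddof=1), 0):
            raise ValueError("zero variance in differences: t undefined")
        t, p = sstats.ttest_rel(x, y)
        return {"t": float(t), "p": float(p), "mean_diff": float(d.mean())}
    if kind == "pearson_bootstrap":
        r, p = sstats.pearsonr(x, y)
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, x.size, size=(n_boot, x.size))
        xb, yb = x[idx], y[idx]
        xm = xb - xb.mean(axis=1, keepdims=True)
        ym = yb - yb.mean(axis=1, keepdims=True)
        denom = np.sqrt((xm**2).sum(axis=1) * (ym**2).sum(axis=1))
        with np.errstate(divide="ignore", invalid="ignore"):
            rb = np.where(denom > 0, (xm * ym).sum(axis=1) / denom, 1.0)
        lo, hi = np.quantile(rb, [(1 - ci_level) / 2, 1 - (1 - ci_level) / 2])
        return {"r": float(r), "p": float(p), "ci": (float(lo), float(hi)),
                "ci_level": ci_level}
    raise ValueError(f"unknown kind: {kind}")
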