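"""Test-retest statistics and time-stability analysis.

Absolute variability of a paired outcome:

    VAR = |x_test - x_retest| / (x_test + x_retest) * 200   [percent]

Intraclass correlation from one-way random-effects ANOVA (the
single-rater, absolute-agreement form often written ICC(1,1)):

    ICC = (MS_B - MS_W) / (MS_B + (k - 1) MS_W)

with MS_B / MS_W the between- and within-subject mean squares over n
subjects and k repeated sessions; the 95% CI follows from F-distribution
bounds on MS_B/MS_W.

Time stability refits a model on progressively truncated scans and
reports V_T relative to the full-duration estimate (100% by
construction at full duration).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .compartment import fit_compartment
from .core import REGION_ORDER, TimeActivityCurve
from .errors import InvalidArgumentError
from .graphical import fit_logan, fit_ma1
from .input_function import InputFunction

__all__ = [
    "TestRetestResult",
    "TimeStabilityResult",
    "absolute_variability",
    "icc_oneway",
    "ICCResult",
    "time_stability",
    "var_by_duration",
    "summarize_study",
    "DEFAULT_DURATIONS_MIN",
]

#: Truncation grid: 33 to 93 min in 6-min (late-frame-length) steps.
DEFAULT_DURATIONS_MIN = tuple(float(d) for d in range(33, 94, 6))


def absolute_variability(vt1, vt2):
    """Test-retest absolute variability in percent (element-wise)."""
    vt1 = np.asarray(vt1, dtype=float)
    vt2 = np.asarray(vt2, dtype=float)
    s = vt1 + vt2
    if np.any(s <= 0):
        raise InvalidArgumentError("test + retest must be > 0")
    out = np.abs(vt1 - vt2) / s * 200.0
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    ms_between: float
    ms_within: float
    n_subjects: int
    k_sessions: int


def icc_oneway(values: np.ndarray, confidence: float = 0.95) -> ICCResult:
    """One-way random-effects ICC of an (n_subjects x k_sessions) matrix."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise InvalidArgumentError("need an (n_subjects x k>=2) matrix")
    n, k = x.shape
    if n < 2:
        raise InvalidArgumentError("need at least 2 subjects")
    grand = x.mean()
    subj_means = x.mean(axis=1)
    ms_b = k * np.sum((subj_means - grand) ** 2) / (n - 1)
    ms_w = np.sum((x - subj_means[:, None]) ** 2) / (n * (k - 1))
    if ms_b + ms_w == 0:
        return ICCResult(np.nan, np.nan, np.nan, ms_b, ms_w, n, k)
    if ms_w == 0:
        return ICCResult(1.0, 1.0, 1.0, ms_b, ms_w, n, k)
    icc = (ms_b - ms_w) / (ms_b + (k - 1) * ms_w)
    alpha = 1.0 - confidence
    f_obs = ms_b / ms_w
    df1, df2 = n - 1, n * (k - 1)
    f_low = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
    f_high = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
    ci_low = (f_low - 1) / (f_low + k - 1)
    ci_high = (f_high - 1) / (f_high + k - 1)
    return ICCResult(float(icc), float(ci_low), float(ci_high), float(ms_b), float(ms_w), n, k)


@dataclass(frozen=True)
class TestRetestResult:
    region_label: str
    model: str
    var_percent_per_subject: np.ndarray
    var_mean: float
    var_sd: float
    icc: float
    icc_ci_low: float
    icc_ci_high: float


@dataclass(frozen=True)
class TimeStabilityResult:
    model: str
    durations_min: np.ndarray
    vt: np.ndarray  # NaN where a duration left too few usable frames
    ratio_to_full_pct: np.ndarray
    region_label: str = ""


def _fit_vt(tac: TimeActivityCurve, input_fn: InputFunction, model: str,
            t_star_min: float, **fit_kwargs) -> float:
    if model in ("1tc", "2tc"):
        return fit_compartment(tac, input_fn, model, **fit_kwargs).vt
    if model == "logan":
        return fit_logan(tac, input_fn, t_star_min).vt
    if model == "ma1":
        return fit_ma1(tac, input_fn, t_star_min).vt
    raise InvalidArgumentError(f"unknown model {model!r}")


def time_stability(
    tac: TimeActivityCurve,
    input_fn: InputFunction,
    model: str = "2tc",
    durations_min=DEFAULT_DURATIONS_MIN,
    t_star_min: float = 27.0,
    **fit_kwargs,
) -> TimeStabilityResult:
    """V_T versus truncated scan duration, normalised to the full scan.

    Each duration keeps only frames ending at or before it and refits
    the model (graphical methods keep the globally fixed t*).  The
    longest duration must equal the full scan, whose ratio is exactly
    100% by construction.  Durations leaving fewer than 3 usable frames
    beyond t* are reported as NaN.
    """
    durations = np.asarray(sorted(durations_min), dtype=float)
    full = tac.schedule.frame_end_min[-1]
    if abs(durations[-1] - full) > 1e-6:
        raise InvalidArgumentError("longest duration must equal the full scan")
    vts = np.full(durations.size, np.nan)
    for j, d in enumerate(durations):
        try:
            vts[j] = _fit_vt(tac.truncated(d), input_fn, model, t_star_min, **fit_kwargs)
        except Exception:
            continue  # flagged missing
    ratio = 100.0 * (vts / vts[-1])  # full-duration entry is exactly 100
    return TimeStabilityResult(model, durations, vts, ratio, tac.region_label)


def var_by_duration(test: TimeStabilityResult, retest: TimeStabilityResult) -> np.ndarray:
    """Paired absolute variability recomputed per truncation duration."""
    if not np.array_equal(test.durations_min, retest.durations_min):
        raise InvalidArgumentError("duration grids differ")
    out = np.full(test.durations_min.size, np.nan)
    ok = np.isfinite(test.vt) & np.isfinite(retest.vt)
    out[ok] = absolute_variability(test.vt[ok], retest.vt[ok])
    return out


def _region_sort_key(region: str):
    try:
        return (0, REGION_ORDER.index(region))
    except ValueError:
        return (1, region)


def summarize_study(fits: pd.DataFrame):
    """Regional V_T summary and test-retest table from a long fit table.

    ``fits`` needs columns subject, session ('test'/'retest'), region,
    model, vt.  Returns ``(vt_table, tr_table)``: per-region/model mean
    and SD of V_T, and per-region/model VAR (mean and SD over subjects)
    with the one-way ICC and its 95% CI.  Regions missing either
    session are dropped with a diagnostic column left out of the table.
    """
    required = {"subject", "session", "region", "model", "vt"}
    if not required.issubset(fits.columns):
        raise InvalidArgumentError(f"fit table needs columns {sorted(required)}")
    regions = sorted(fits["region"].unique(), key=_region_sort_key)
    vt_rows, tr_rows = [], []
    for region in regions:
        for model in sorted(fits["model"].unique()):
            sub = fits[(fits.region == region) & (fits.model == model)]
            vt_rows.append(
                {
                    "region": region,
                    "model": model,
                    "vt_mean": sub.vt.mean(),
                    "vt_sd": sub.vt.std(ddof=1),
                    "n": len(sub),
                }
            )
            wide = sub.pivot_table(index="subject", columns="session", values="vt")
            if not {"test", "retest"}.issubset(wide.columns):
                continue
            wide = wide.dropna(subset=["test", "retest"])
            if len(wide) < 2:
                continue
            var = absolute_variability(wide["test"].to_numpy(), wide["retest"].to_numpy())
            icc = icc_oneway(wide[["test", "retest"]].to_numpy())
            tr_rows.append(
                {
                    "region": region,
                    "model": model,
                    "var_mean_pct": float(np.mean(var)),
                    "var_sd_pct": float(np.std(var, ddof=1)) if var.size > 1 else 0.0,
                    "icc": icc.icc,
                    "icc_ci_low": icc.ci_low,
                    "icc_ci_high": icc.ci_high,
                    "n_subjects": len(wide),
                }
            )
    return pd.DataFrame(vt_rows), pd.DataFrame(tr_rows)
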