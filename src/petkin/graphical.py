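"""Logan graphical analysis and MA1 multilinear analysis.

Both methods linearize the reversible-tracer kinetics after a start
time t* beyond which the plot is effectively linear:

* Logan:  int_0^t C_T / C_T(t)  =  V_T * int_0^t Cp / C_T(t)  +  b
  (ordinary least squares; the slope is V_T),
* MA1:    C_T(t) = -(V_T/b) int_0^t Cp + (1/b) int_0^t C_T
  (multilinear regression on the two integral regressors;
  V_T = -beta1/beta2).

MA1 keeps the noisy measurement on the left-hand side only, which is
why it suffers less from the noise-induced negative bias of the Logan
slope.  t* is chosen by the "Max Err" criterion: the earliest frame
boundary such that every included point deviates from the fitted line
by at most a given relative error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._kernels import cumtrapz_grid
from .core import TimeActivityCurve
from .errors import FitError, InvalidArgumentError
from .input_function import InputFunction

__all__ = [
    "GraphicalFit",
    "TStarResult",
    "AgreementSummary",
    "fit_logan",
    "fit_ma1",
    "select_tstar",
    "compare_to_2tc",
]


@dataclass(frozen=True)
class GraphicalFit:
    method: str  # "logan" or "ma1"
    vt: float
    second_param: float  # Logan: intercept; MA1: b (the 1/beta2 time constant)
    t_star_min: float
    n_frames_used: int
    percent_se_vt: float
    max_err_pct: float  # max |relative residual| of the included points
    region_label: str = ""


@dataclass(frozen=True)
class TStarResult:
    t_star_min: float
    criterion_met: bool
    max_err_pct: float
    method: str


@dataclass(frozen=True)
class AgreementSummary:
    """Graphical-vs-2TC percent differences plus Bland-Altman pairs."""

    method: str
    mean_pct_diff: float
    sd_pct_diff: float
    pairs: "object"  # DataFrame: keys, vt_graphical, vt_2tc, mean_vt, pct_diff


def _integrated_curves(tac: TimeActivityCurve, input_fn: InputFunction):
    """Tissue and plasma running integrals evaluated at frame midpoints.

    The tissue integral is a trapezoid over midpoints with a zero anchor
    at t = 0 (frames do not start sampling at injection); the plasma
    integral is exact for the piecewise-linear fine-grid input.
    """
    mid = tac.midpoints_min
    ct = tac.activity
    t_anchor = np.concatenate([[0.0], mid])
    c_anchor = np.concatenate([[0.0], ct])
    int_ct = np.cumsum(
        0.5 * (c_anchor[1:] + c_anchor[:-1]) * np.diff(t_anchor)
    )
    icp_grid = cumtrapz_grid(input_fn.time_min, input_fn.plasma_parent_kbq_cc)
    int_cp = np.interp(mid, input_fn.time_min, icp_grid)
    return mid, ct, int_ct, int_cp


def _usable(tac, input_fn, t_star_min):
    mid, ct, int_ct, int_cp = _integrated_curves(tac, input_fn)
    mask = mid >= t_star_min - 1e-9
    bad = mask & (ct <= 0)
    if np.any(bad):
        warnings.warn(
            f"excluding {int(np.sum(bad))} non-positive frame(s) from the graphical fit",
            stacklevel=3,
        )
        mask &= ct > 0
    if np.count_nonzero(mask) < 3:
        raise FitError(f"fewer than 3 usable frames beyond t* = {t_star_min} min")
    return mid[mask], ct[mask], int_ct[mask], int_cp[mask]


def fit_logan(
    tac: TimeActivityCurve, input_fn: InputFunction, t_star_min: float
) -> GraphicalFit:
    """Logan plot over frames with midpoint >= t*; V_T is the OLS slope."""
    _, ct, int_ct, int_cp = _usable(tac, input_fn, t_star_min)
    x = int_cp / ct
    y = int_ct / ct
    res = stats.linregress(x, y)
    y_hat = res.intercept + res.slope * x
    max_err = 100.0 * float(np.max(np.abs((y - y_hat) / y_hat)))
    pse = 100.0 * res.stderr / abs(res.slope) if res.slope != 0 else np.nan
    return GraphicalFit(
        method="logan",
        vt=float(res.slope),
        second_param=float(res.intercept),
        t_star_min=float(t_star_min),
        n_frames_used=int(x.size),
        percent_se_vt=float(pse),
        max_err_pct=max_err,
        region_label=tac.region_label,
    )


def fit_ma1(
    tac: TimeActivityCurve, input_fn: InputFunction, t_star_min: float
) -> GraphicalFit:
    """MA1 multilinear fit; V_T = -beta1/beta2, %SE by the delta method."""
    _, ct, int_ct, int_cp = _usable(tac, input_fn, t_star_min)
    X = np.column_stack([int_cp, int_ct])
    beta, res_ss, rank, _ = np.linalg.lstsq(X, ct, rcond=None)
    if rank < 2:
        raise FitError("collinear MA1 regressors")
    b1, b2 = beta
    if b2 == 0:
        raise FitError("degenerate MA1 fit (beta2 = 0)")
    vt = -b1 / b2
    n = ct.size
    y_hat = X @ beta
    resid = ct - y_hat
    dof = n - 2
    s2 = float(resid @ resid) / dof if dof > 0 else np.nan
    cov = s2 * np.linalg.pinv(X.T @ X)
    g = np.array([-1.0 / b2, b1 / (b2 * b2)])
    var_vt = float(g @ cov @ g)
    pse = 100.0 * np.sqrt(var_vt) / abs(vt) if var_vt >= 0 and vt != 0 else np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(resid / y_hat)
    max_err = 100.0 * float(np.nanmax(rel))
    return GraphicalFit(
        method="ma1",
        vt=float(vt),
        second_param=float(1.0 / b2),
        t_star_min=float(t_star_min),
        n_frames_used=int(n),
        percent_se_vt=float(pse),
        max_err_pct=max_err,
        region_label=tac.region_label,
    )


_FITTERS = {"logan": fit_logan, "ma1": fit_ma1}


def select_tstar(
    tac: TimeActivityCurve,
    input_fn: InputFunction,
    method: str = "logan",
    max_err_pct: float = 10.0,
) -> TStarResult:
    """Earliest frame-boundary t* whose Max Err is within the threshold.

    Candidates are frame start times in ascending order; the first one
    leaving >= 3 usable frames and a maximum relative deviation of the
    included points from the fitted line <= ``max_err_pct`` wins.  If no
    candidate qualifies the latest admissible start is returned with
    ``criterion_met = False``.
    """
    if method not in _FITTERS:
        raise InvalidArgumentError(f"unknown graphical method {method!r}")
    if tac.schedule.n_frames < 10:
        raise InvalidArgumentError("t* selection needs >= 10 frames")
    fitter = _FITTERS[method]
    last = None
    for t_cand in tac.schedule.frame_start_min:
        try:
            fit = fitter(tac, input_fn, float(t_cand))
        except FitError:
            break
        last = fit
        if fit.max_err_pct <= max_err_pct:
            return TStarResult(float(t_cand), True, fit.max_err_pct, method)
    if last is None:
        raise FitError("no admissible t* candidate (too few frames)")
    return TStarResult(last.t_star_min, False, last.max_err_pct, method)


def compare_to_2tc(graphical, compartment, keys=("subject", "session", "region")):
    """Percent difference of graphical V_T relative to 2TC V_T, pairwise.

    Both arguments are DataFrames with the pairing ``keys`` and a ``vt``
    column; rows are matched one-to-one on the keys.  Returns an
    :class:`AgreementSummary` whose ``pairs`` table carries the
    Bland-Altman coordinates (mean of the two estimates vs percent
    difference).
    """
    import pandas as pd

    keys = list(keys)
    g = pd.DataFrame(graphical)
    c = pd.DataFrame(compartment)
    for df, nm in ((g, "graphical"), (c, "compartment")):
        if df.duplicated(keys).any():
            raise InvalidArgumentError(f"duplicate pairing keys in {nm} table")
    merged = g.merge(c, on=keys, how="outer", suffixes=("_graphical", "_2tc"), indicator=True)
    if (merged["_merge"] != "both").any():
        raise InvalidArgumentError("mismatched pairing keys between the two fit tables")
    merged = merged.drop(columns="_merge")
    pct = 100.0 * (merged["vt_graphical"] - merged["vt_2tc"]) / merged["vt_2tc"]
    merged["pct_diff"] = pct
    merged["mean_vt"] = 0.5 * (merged["vt_graphical"] + merged["vt_2tc"])
    method = str(g["method"].iloc[0]) if "method" in g.columns else "graphical"
    return AgreementSummary(
        method=method,
        mean_pct_diff=float(pct.mean()),
        sd_pct_diff=float(pct.std(ddof=1)) if len(pct) > 1 else 0.0,
        pairs=merged,
    )
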