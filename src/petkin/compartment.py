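"""Plasma-input compartment models (1TC, 2TC) and model-selection scores.

The measured PET signal is modelled as

    C_model(t) = (1 - vB) * C_tissue(t) + vB * C_wb(t)

where C_wb is whole-blood activity and C_tissue solves

    1TC:  dC1/dt = K1 Cp - k2 C1,                    C_tissue = C1
    2TC:  dC1/dt = K1 Cp - (k2 + k3) C1 + k4 C2
          dC2/dt = k3 C1 - k4 C2,                    C_tissue = C1 + C2

driven by the metabolite-corrected plasma input Cp.  The tissue
response is a sum of (at most two) exponentials convolved with Cp; the
convolution against the piecewise-linear input is evaluated in closed
form per grid segment (see :mod:`petkin._kernels`), and the predicted
frame value is the exact time-average of the continuous model over the
frame.  The outcome measure is the total distribution volume

    V_T = K1/k2              (1TC)
    V_T = K1/k2 (1 + k3/k4)  (2TC)
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from ._kernels import cumtrapz_grid, exp_conv
from .core import FrameSchedule, TimeActivityCurve
from .errors import FitError, InvalidArgumentError
from .input_function import InputFunction

__all__ = [
    "CompartmentParams",
    "KineticFit",
    "model_tac",
    "model_curve",
    "fit_compartment",
    "aic",
    "msc",
    "total_distribution_volume",
]

RATE_BOUNDS = (1e-6, 10.0)  # 1/min (K1 shares the numeric range, mL/ccm/min)
VB_BOUNDS = (0.0, 0.2)


@dataclass(frozen=True)
class CompartmentParams:
    """Micro-parameters of a compartment model (2TC superset)."""

    K1: float  # mL/ccm/min
    k2: float  # 1/min
    k3: float = 0.0
    k4: float = 0.0
    vB: float = 0.0


def total_distribution_volume(model: str, p: CompartmentParams) -> float:
    """V_T from micro-parameters; +inf for the irreversible 2TC limit k4=0."""
    if model == "1tc":
        return p.K1 / p.k2
    if model == "2tc":
        if p.k4 == 0.0:
            return math.inf if p.k3 > 0 else p.K1 / p.k2
        return (p.K1 / p.k2) * (1.0 + p.k3 / p.k4)
    raise InvalidArgumentError(f"unknown model {model!r}")


def _impulse_terms(model: str, p: CompartmentParams) -> list[tuple[float, float]]:
    """Tissue impulse response K1 * sum_j amp_j exp(-rate_j t) as (amp, rate)."""
    if model == "1tc":
        return [(1.0, p.k2)]
    if model == "2tc":
        theta = p.k2 + p.k3 + p.k4
        disc = math.sqrt(max(theta * theta - 4.0 * p.k2 * p.k4, 0.0))
        if disc < 1e-12:
            disc = 1e-12  # coincident eigenvalues; nudge off the degenerate point
        a_slow = (theta - disc) / 2.0
        a_fast = (theta + disc) / 2.0
        return [
            ((p.k3 + p.k4 - a_slow) / disc, a_slow),
            ((a_fast - p.k3 - p.k4) / disc, a_fast),
        ]
    raise InvalidArgumentError(f"unknown model {model!r}")


def model_curve(
    model: str, params: CompartmentParams, input_fn: InputFunction
) -> np.ndarray:
    """Continuous model prediction sampled on the input's fine grid."""
    t = input_fn.time_min
    cp = input_fn.plasma_parent_kbq_cc
    tissue = np.zeros_like(t)
    for amp, rate in _impulse_terms(model, params):
        y, _ = exp_conv(t, cp, rate)
        tissue = tissue + amp * y
    tissue *= params.K1
    return (1.0 - params.vB) * tissue + params.vB * input_fn.whole_blood_kbq_cc


def model_tac(
    model: str,
    params: CompartmentParams,
    input_fn: InputFunction,
    schedule: FrameSchedule,
) -> np.ndarray:
    """Frame-averaged model prediction (one value per frame).

    The running integral of the convolution has a closed form on each
    input segment, so frame averages are exact up to the piecewise-
    linear representation of the input itself.
    """
    t = input_fn.time_min
    if schedule.frame_end_min[-1] > t[-1] + 1e-6:
        raise InvalidArgumentError("schedule extends beyond the input grid")
    cp = input_fn.plasma_parent_kbq_cc
    z_total = np.zeros_like(t)
    for amp, rate in _impulse_terms(model, params):
        _, z = exp_conv(t, cp, rate)
        z_total = z_total + amp * z
    z_total *= params.K1 * (1.0 - params.vB)
    if params.vB != 0.0:
        z_total = z_total + params.vB * cumtrapz_grid(t, input_fn.whole_blood_kbq_cc)
    z_lo = np.interp(schedule.frame_start_min, t, z_total)
    z_hi = np.interp(schedule.frame_end_min, t, z_total)
    return (z_hi - z_lo) / schedule.frame_duration_min


def aic(rss_weighted: float, n: int, p: int) -> float:
    """Akaike information criterion, AIC = n ln(RSS/n) + 2p (lower is better)."""
    if rss_weighted <= 0:
        raise InvalidArgumentError("weighted RSS must be > 0")
    if n <= p:
        raise InvalidArgumentError("need more observations than parameters")
    return n * math.log(rss_weighted / n) + 2 * p


def msc(y: np.ndarray, y_hat: np.ndarray, p: int, weights: np.ndarray | None = None) -> float:
    """Model selection criterion (higher is better).

    MSC = ln( sum w (y - ybar_w)^2 / sum w (y - yhat)^2 ) - 2p/n,
    with ybar_w the weighted mean of the data.
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    n = y.size
    ybar = np.sum(w * y) / np.sum(w)
    ss_tot = float(np.sum(w * (y - ybar) ** 2))
    if ss_tot <= 0:
        raise InvalidArgumentError("data are constant; MSC undefined")
    ss_res = float(np.sum(w * (y - y_hat) ** 2))
    if ss_res == 0.0:
        return math.inf
    return math.log(ss_tot / ss_res) - 2.0 * p / n


@dataclass(frozen=True)
class KineticFit:
    """Result of a compartment-model fit to one regional TAC."""

    model: str
    params: CompartmentParams
    vt: float
    percent_se_vt: float  # NaN when the covariance is singular
    rss: float  # weighted residual sum of squares
    aic: float
    msc: float
    n_frames_used: int
    converged: bool
    n_free_params: int = 0
    region_label: str = ""


def _frame_weights(tac: TimeActivityCurve, mode: str) -> np.ndarray:
    if mode == "uniform":
        return np.ones_like(tac.activity)
    if mode == "duration":
        # classic count-statistics proxy: w ~ duration / activity
        floor = max(1e-3, 0.01 * float(np.max(np.abs(tac.activity))))
        return tac.schedule.frame_duration_min / np.maximum(np.abs(tac.activity), floor)
    raise InvalidArgumentError(f"unknown weights mode {mode!r}")


def _pack(model: str, vb_mode: str):
    names = ["K1", "k2"] if model == "1tc" else ["K1", "k2", "k3", "k4"]
    if vb_mode == "fit":
        names.append("vB")
    return names


def _to_params(x: np.ndarray, names: list[str], vb_fixed: float) -> CompartmentParams:
    d = dict(zip(names, x))
    return CompartmentParams(
        K1=d["K1"],
        k2=d["k2"],
        k3=d.get("k3", 0.0),
        k4=d.get("k4", 0.0),
        vB=d.get("vB", vb_fixed),
    )


def _vt_gradient(model: str, p: CompartmentParams, names: list[str]) -> np.ndarray:
    vt = total_distribution_volume(model, p)
    grad = {
        "K1": vt / p.K1,
        "k2": -vt / p.k2,
        "vB": 0.0,
    }
    if model == "2tc" and p.k4 > 0:
        grad["k3"] = (p.K1 / p.k2) / p.k4
        grad["k4"] = -(p.K1 / p.k2) * p.k3 / (p.k4 * p.k4)
    else:
        grad["k3"] = grad["k4"] = 0.0
    return np.array([grad[n] for n in names])


def fit_compartment(
    tac: TimeActivityCurve,
    input_fn: InputFunction,
    model: str = "2tc",
    weights_mode: str = "uniform",
    vb_mode: str = "fit",
    vb_fixed: float = 0.05,
) -> KineticFit:
    """Weighted nonlinear least-squares fit of a compartment model.

    Rates are bounded to [1e-6, 10] / min and vB to [0, 0.2]; the fit is
    multi-started from a deterministic grid.  For the 2TC the converged
    1TC solution seeds an extra start with k3 -> 0, which guarantees the
    nested-model property (2TC weighted RSS <= 1TC weighted RSS).
    ``percent_se_vt`` is propagated from the parameter covariance by the
    delta method.
    """
    if model not in ("1tc", "2tc"):
        raise InvalidArgumentError(f"unknown model {model!r}")
    if vb_mode not in ("fit", "fixed"):
        raise InvalidArgumentError(f"unknown vB mode {vb_mode!r}")
    names = _pack(model, vb_mode)
    n = tac.schedule.n_frames
    if n < len(names) + 2:
        raise InvalidArgumentError(f"need >= {len(names) + 2} frames to fit {model}")

    w = _frame_weights(tac, weights_mode)
    sw = np.sqrt(w)
    obs = tac.activity
    sched = tac.schedule

    def resid(x):
        p = _to_params(x, names, vb_fixed)
        return sw * (model_tac(model, p, input_fn, sched) - obs)

    lb = np.array([RATE_BOUNDS[0]] * (len(names) - (1 if "vB" in names else 0)) + ([VB_BOUNDS[0]] if "vB" in names else []))
    ub = np.array([RATE_BOUNDS[1]] * (len(names) - (1 if "vB" in names else 0)) + ([VB_BOUNDS[1]] if "vB" in names else []))

    starts: list[np.ndarray] = []
    vb0 = 0.05 if "vB" in names else None

    def mk(**kw):
        vals = {"K1": 0.3, "k2": 0.2, "k3": 0.05, "k4": 0.03, "vB": vb0}
        vals.update(kw)
        return np.array([vals[nm] for nm in names])

    if model == "1tc":
        for k1 in (0.1, 0.5):
            for k2 in (0.05, 0.2, 0.8):
                starts.append(mk(K1=k1, k2=k2))
    else:
        # seed from the nested 1TC solution
        fit1 = fit_compartment(tac, input_fn, "1tc", weights_mode, vb_mode, vb_fixed)
        starts.append(
            mk(K1=fit1.params.K1, k2=fit1.params.k2, k3=RATE_BOUNDS[0], k4=0.05,
               vB=fit1.params.vB if vb0 is not None else None)
        )
        for k2 in (0.15, 0.5):
            for k3 in (0.03, 0.1):
                starts.append(mk(K1=0.3, k2=k2, k3=k3, k4=0.03))

    best = None
    for x0 in starts:
        x0 = np.clip(x0, lb, ub)
        try:
            sol = least_squares(
                resid, x0, bounds=(lb, ub), method="trf",
                xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=2000,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost - 1e-300:
            best = sol
    if best is None:
        raise FitError(f"{model} fit failed from every start for {tac.region_label!r}")

    p_hat = _to_params(best.x, names, vb_fixed)
    vt = total_distribution_volume(model, p_hat)
    rss = float(2.0 * best.cost)
    n_par = len(names)

    percent_se = math.nan
    dof = n - n_par
    if dof > 0 and math.isfinite(vt) and vt != 0:
        jtj = best.jac.T @ best.jac
        try:
            cov = np.linalg.pinv(jtj) * (rss / dof)
            g = _vt_gradient(model, p_hat, names)
            var_vt = float(g @ cov @ g)
            if var_vt >= 0:
                percent_se = 100.0 * math.sqrt(var_vt) / abs(vt)
        except np.linalg.LinAlgError:
            pass

    pred = model_tac(model, p_hat, input_fn, sched)
    return KineticFit(
        model=model,
        params=p_hat,
        vt=vt,
        percent_se_vt=percent_se,
        rss=rss,
        aic=aic(max(rss, 1e-300), n, n_par),
        msc=msc(obs, pred, n_par, w),
        n_frames_used=n,
        converged=bool(best.status > 0),
        n_free_params=n_par,
        region_label=tac.region_label,
    )
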