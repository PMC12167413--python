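"""Synthetic test-retest PET studies with known ground truth.

The generator emulates a six-subject test-retest study of a rapidly
metabolised, reversibly binding brain radioligand on a 38-frame, 93-min
acquisition:

* plasma total activity follows a delayed Feng-type tri-exponential
  (linear rise to an early peak, then multi-exponential decay),
* the parent fraction decays tri-exponentially from 1, reaching
  0.10-0.20 by 20 min (rapid metabolism),
* regional tissue kinetics follow the 2TC model, with population
  V_T rank order pons > thalamus ~ putamen > frontal cortex >
  cerebellum and whole-brain peak SUV in the 4.3-6.3 range,
* between-subject and test-retest (within-subject) variability enter as
  log-normal multipliers on the micro-parameters, and frame noise is
  zero-mean Gaussian with SD proportional to sqrt(activity / duration)
  (a count-statistics proxy).

Tissue curves are produced by direct ODE integration (``solve_ivp``
with an integrated-activity auxiliary state for exact frame averages),
deliberately a different numerical route from the closed-form
convolution the fitting code uses, so each can serve as an oracle for
the other.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .core import (
    BloodSampleTable,
    FrameSchedule,
    ParentFractionTable,
    SubjectMeta,
    TimeActivityCurve,
    hrrt_38_frame_schedule,
)
from .errors import InvalidArgumentError
from .input_function import InputFunction, default_fine_grid

__all__ = [
    "InputFunctionParams",
    "ParentFractionParams",
    "RegionKineticTruth",
    "StudyDesign",
    "SessionData",
    "SimulatedStudy",
    "DEFAULT_INPUT_PARAMS",
    "DEFAULT_PARENT_PARAMS",
    "DEFAULT_REGIONS",
    "REFERENCE_DEMOGRAPHICS",
    "simulate_input_function",
    "simulate_parent_fraction",
    "simulate_true_input",
    "simulate_tissue_tac",
    "simulate_study",
]

MANUAL_SAMPLE_TIMES_MIN = np.array([2.0, 4, 6, 8, 10, 15, 20, 30, 45, 60, 90])
PARENT_SAMPLE_TIMES_MIN = np.array([2.0, 4, 6, 8, 10, 15, 20, 30, 45, 60])


@dataclass(frozen=True)
class InputFunctionParams:
    """Feng-type tri-exponential plasma total-activity model.

    Cp(t) = (a1 (t-d) - a2 - a3) e^{l1 (t-d)} + a2 e^{l2 (t-d)}
            + a3 e^{l3 (t-d)}   for t >= d, else 0,

    with l1 < l2 < l3 < 0 (l1 the most negative eigenrate drives the
    fast post-peak drop) and d the arrival delay.  Cp(d) = 0 and the
    curve rises roughly linearly with slope a1 to a single early peak.
    """

    a1: float  # kBq/cc/min
    a2: float  # kBq/cc
    a3: float  # kBq/cc
    l1: float  # 1/min
    l2: float  # 1/min
    l3: float  # 1/min
    delay_min: float = 0.0

    def __post_init__(self) -> None:
        if not (self.l1 <= self.l2 <= self.l3 < 0):
            raise InvalidArgumentError("need l1 <= l2 <= l3 < 0 for a peak-then-decay shape")
        if self.a1 <= 0 or self.a2 < 0 or self.a3 < 0:
            raise InvalidArgumentError("amplitudes must be positive (a1) / non-negative")


@dataclass(frozen=True)
class ParentFractionParams:
    """Tri-exponential parent fraction: pf(t) = sum c_i exp(-mu_i t), pf(0) = 1."""

    c: tuple[float, float, float]
    mu: tuple[float, float, float]  # 1/min, >= 0 (0 allows a plateau)

    def __post_init__(self) -> None:
        if abs(sum(self.c) - 1.0) > 1e-9:
            raise InvalidArgumentError("parent-fraction weights must sum to 1")
        if any(ci < 0 for ci in self.c) or any(m < 0 for m in self.mu):
            raise InvalidArgumentError("weights and decay rates must be non-negative")


@dataclass(frozen=True)
class RegionKineticTruth:
    """Ground-truth 2TC micro-parameters for one region."""

    region_label: str
    K1: float  # mL/ccm/min
    k2: float  # 1/min
    k3: float  # 1/min
    k4: float  # 1/min
    vB: float = 0.05

    def __post_init__(self) -> None:
        if min(self.K1, self.k2, self.k3, self.k4) <= 0:
            raise InvalidArgumentError("all rates must be > 0")
        if not 0 <= self.vB <= 0.1:
            raise InvalidArgumentError("vB must lie in [0, 0.1]")

    @property
    def vt(self) -> float:
        return (self.K1 / self.k2) * (1.0 + self.k3 / self.k4)


#: Default plasma model; amplitudes set so that with the default regional
#: kinetics and a typical injected dose per body weight (~5.6 MBq/kg) the
#: whole-brain peak SUV lands in the 4.3-6.3 range.
DEFAULT_INPUT_PARAMS = InputFunctionParams(
    a1=985.0, a2=18.5, a3=11.0, l1=-4.5, l2=-0.35, l3=-0.022, delay_min=0.4,
)

#: Default parent-fraction model; pf(20 min) ~ 0.15 (rapid metabolism).
DEFAULT_PARENT_PARAMS = ParentFractionParams(
    c=(0.75, 0.20, 0.05), mu=(0.28, 0.035, 0.0),
)

#: Population-mean regional kinetics.  V_T rank order pons > thalamus >
#: putamen > frontal cortex > cerebellum; pons carries the slowest
#: washout (white-matter admixture), cortex/cerebellum the fastest.
DEFAULT_REGIONS: tuple[RegionKineticTruth, ...] = (
    RegionKineticTruth("pons", K1=0.60, k2=0.1583, k3=0.125, k4=0.205),
    RegionKineticTruth("thalamus", K1=0.58, k2=0.1687, k3=0.120, k4=0.200),
    RegionKineticTruth("putamen", K1=0.56, k2=0.1686, k3=0.118, k4=0.198),
    RegionKineticTruth("frontal_cortex", K1=0.55, k2=0.2201, k3=0.122, k4=0.203),
    RegionKineticTruth("cerebellum", K1=0.54, k2=0.2380, k3=0.115, k4=0.196),
)

#: Demographics of the six-subject healthy-volunteer reference study the
#: generator emulates: age (years) and injected activity (MBq) for the
#: test and retest sessions, plus body weights back-computed from the
#: reported BMI assuming a 1.70 m stature.
REFERENCE_DEMOGRAPHICS = pd.DataFrame(
    {
        "subject_id": ["s01", "s02", "s03", "s04", "s05", "s06"],
        "age_years": [21, 21, 21, 24, 22, 30],
        "bmi_kg_m2": [25.7, 20.5, 22.9, 21.9, 21.5, 20.2],
        "injected_test_mbq": [510.0, 398.0, 297.0, 337.0, 335.0, 310.0],
        "injected_retest_mbq": [539.0, 386.0, 334.0, 350.0, 364.0, 316.0],
    }
).assign(body_weight_kg=lambda d: d.bmi_kg_m2 * 1.70**2)


@dataclass(frozen=True)
class StudyDesign:
    """Population and noise settings of a simulated test-retest study."""

    n_subjects: int = 6
    regions: tuple[RegionKineticTruth, ...] = DEFAULT_REGIONS
    between_subject_cv: float = 0.20
    within_subject_cv: float = 0.03
    noise_scale: float = 0.10
    blood_noise_frac: float = 0.02
    parent_noise_sd: float = 0.02
    input_params: InputFunctionParams = DEFAULT_INPUT_PARAMS
    parent_params: ParentFractionParams = DEFAULT_PARENT_PARAMS
    plasma_to_blood_ratio: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise InvalidArgumentError("need at least one subject")
        if self.between_subject_cv < 0 or self.within_subject_cv < 0:
            raise InvalidArgumentError("CVs must be >= 0")


def simulate_input_function(params: InputFunctionParams, grid_min: np.ndarray) -> np.ndarray:
    """Plasma total-activity curve on ``grid_min`` (0 before the delay)."""
    t = np.asarray(grid_min, dtype=float)
    tt = t - params.delay_min
    pos = np.maximum(tt, 0.0)
    cp = (
        (params.a1 * pos - params.a2 - params.a3) * np.exp(params.l1 * pos)
        + params.a2 * np.exp(params.l2 * pos)
        + params.a3 * np.exp(params.l3 * pos)
    )
    cp = np.where(tt < 0, 0.0, cp)
    return np.clip(cp, 0.0, None)


def simulate_parent_fraction(params: ParentFractionParams, times_min) -> np.ndarray:
    """pf(t) = sum c_i exp(-mu_i t); monotone non-increasing from pf(0) = 1."""
    t = np.asarray(times_min, dtype=float)
    pf = np.zeros_like(t)
    for c, mu in zip(params.c, params.mu):
        pf = pf + c * np.exp(-mu * t)
    return pf


def simulate_true_input(
    input_params: InputFunctionParams = DEFAULT_INPUT_PARAMS,
    parent_params: ParentFractionParams = DEFAULT_PARENT_PARAMS,
    grid_min: np.ndarray | None = None,
    plasma_to_blood_ratio: float = 1.0,
    amplitude: float = 1.0,
) -> InputFunction:
    """Noise-free ground-truth input: parent plasma + whole blood curves."""
    if grid_min is None:
        grid_min = default_fine_grid()
    cp_total = amplitude * simulate_input_function(input_params, grid_min)
    pf = simulate_parent_fraction(parent_params, grid_min)
    return InputFunction(
        time_min=np.asarray(grid_min, dtype=float),
        plasma_parent_kbq_cc=cp_total * pf,
        whole_blood_kbq_cc=cp_total / plasma_to_blood_ratio,
    )


def simulate_tissue_tac(
    truth: RegionKineticTruth,
    input_fn: InputFunction,
    schedule: FrameSchedule | None = None,
    noise_scale: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> TimeActivityCurve:
    """Frame-averaged (optionally noisy) tissue TAC by ODE integration.

    The 2TC state is augmented with z(t) = int C_model dt so each frame
    value is the exact time-average of the continuous model over the
    frame (up to integrator tolerance).  Noise is zero-mean Gaussian per
    frame with SD = noise_scale * sqrt(C_model(mid) / duration).
    """
    if schedule is None:
        schedule = hrrt_38_frame_schedule()
    tgrid = input_fn.time_min
    if schedule.frame_end_min[-1] > tgrid[-1] + 1e-6:
        raise InvalidArgumentError("schedule extends beyond the input grid")
    cp = input_fn.plasma_parent_kbq_cc
    wb = input_fn.whole_blood_kbq_cc
    K1, k2, k3, k4, vB = truth.K1, truth.k2, truth.k3, truth.k4, truth.vB

    def rhs(t, y):
        cpt = np.interp(t, tgrid, cp)
        c1, c2, _ = y
        dc1 = K1 * cpt - (k2 + k3) * c1 + k4 * c2
        dc2 = k3 * c1 - k4 * c2
        cmod = (1.0 - vB) * (c1 + c2) + vB * np.interp(t, tgrid, wb)
        return (dc1, dc2, cmod)

    bounds = np.concatenate([schedule.frame_start_min, schedule.frame_end_min[-1:]])
    mids = schedule.midpoints_min
    t_eval = np.unique(np.concatenate([bounds, mids]))
    sol = solve_ivp(
        rhs, (0.0, float(bounds[-1])), (0.0, 0.0, 0.0),
        t_eval=t_eval, method="LSODA", rtol=1e-10, atol=1e-12, max_step=0.05,
    )
    if not sol.success:
        raise RuntimeError(f"tissue ODE integration failed: {sol.message}")
    z = np.interp(bounds, sol.t, sol.y[2])
    frames = np.diff(z) / schedule.frame_duration_min
    if noise_scale > 0:
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        c1m = np.interp(mids, sol.t, sol.y[0])
        c2m = np.interp(mids, sol.t, sol.y[1])
        cmid = (1.0 - vB) * (c1m + c2m) + vB * np.interp(mids, tgrid, wb)
        sd = noise_scale * np.sqrt(np.maximum(cmid, 0.0) / schedule.frame_duration_min)
        frames = frames + gen.normal(0.0, 1.0, size=frames.size) * sd
    return TimeActivityCurve(schedule, frames, region_label=truth.region_label)


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Mean-1 log-normal multiplier with coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


@dataclass(frozen=True)
class SessionData:
    """Everything one PET session contributes to the analysis."""

    meta: SubjectMeta
    abss: BloodSampleTable
    manual: BloodSampleTable
    parent_samples: ParentFractionTable
    tacs: dict
    true_input: InputFunction
    truths: dict


@dataclass(frozen=True)
class SimulatedStudy:
    design: StudyDesign
    schedule: FrameSchedule
    sessions: dict  # (subject_id, session) -> SessionData
    ground_truth: pd.DataFrame

    def session(self, subject_id: str, session: str) -> SessionData:
        return self.sessions[(subject_id, session)]


def simulate_study(design: StudyDesign) -> SimulatedStudy:
    """Simulate a complete test-retest study with known ground truth.

    Subject-level micro-parameters are drawn log-normally around the
    population means with ``between_subject_cv``; each session re-jitters
    them with ``within_subject_cv``.  Injected activities and body
    weights follow the reference demographics for the first six
    subjects and are drawn log-normally beyond that.  All randomness
    derives deterministically from ``design.seed``.
    """
    schedule = hrrt_38_frame_schedule()
    grid = default_fine_grid()
    ref = REFERENCE_DEMOGRAPHICS
    ref_dose_per_kg = float(
        (ref.injected_test_mbq.mean() + ref.injected_retest_mbq.mean())
        / 2.0 / ref.body_weight_kg.mean()
    )
    root = np.random.SeedSequence(design.seed)
    subj_seeds = root.spawn(design.n_subjects)

    sessions: dict = {}
    truth_rows = []
    for i in range(design.n_subjects):
        subject_id = f"s{i + 1:02d}"
        children = subj_seeds[i].spawn(3)
        s_rng = np.random.default_rng(children[0])
        sess_rngs = {
            "test": np.random.default_rng(children[1]),
            "retest": np.random.default_rng(children[2]),
        }
        # subject-level kinetics
        subj_regions = []
        for reg in design.regions:
            f = _lognormal_factor(s_rng, design.between_subject_cv, size=4)
            subj_regions.append(
                replace(reg, K1=reg.K1 * f[0], k2=reg.k2 * f[1], k3=reg.k3 * f[2], k4=reg.k4 * f[3])
            )
        if i < len(ref):
            weight = float(ref.body_weight_kg[i])
            injected = {
                "test": float(ref.injected_test_mbq[i]),
                "retest": float(ref.injected_retest_mbq[i]),
            }
        else:
            weight = float(65.0 * _lognormal_factor(s_rng, 0.10))
            injected = {
                "test": float(373.0 * _lognormal_factor(s_rng, 0.15)),
                "retest": float(373.0 * _lognormal_factor(s_rng, 0.15)),
            }

        for session in ("test", "retest"):
            rng = sess_rngs[session]
            meta = SubjectMeta(subject_id, session, injected[session], weight)
            amplitude = (meta.injected_activity_mbq / meta.body_weight_kg) / ref_dose_per_kg
            true_input = simulate_true_input(
                design.input_params,
                design.parent_params,
                grid,
                design.plasma_to_blood_ratio,
                amplitude=amplitude,
            )
            truths = {}
            tacs = {}
            for reg in subj_regions:
                f = _lognormal_factor(rng, design.within_subject_cv, size=4)
                truth = replace(
                    reg, K1=reg.K1 * f[0], k2=reg.k2 * f[1], k3=reg.k3 * f[2], k4=reg.k4 * f[3]
                )
                truths[truth.region_label] = truth
                tacs[truth.region_label] = simulate_tissue_tac(
                    truth, true_input, schedule, design.noise_scale, rng
                )
                truth_rows.append(
                    {
                        "subject": subject_id,
                        "session": session,
                        "region": truth.region_label,
                        "K1": truth.K1,
                        "k2": truth.k2,
                        "k3": truth.k3,
                        "k4": truth.k4,
                        "vB": truth.vB,
                        "vt": truth.vt,
                    }
                )
            sessions[(subject_id, session)] = SessionData(
                meta=meta,
                abss=_abss_table(true_input, design, rng),
                manual=_manual_table(true_input, design, rng),
                parent_samples=_parent_table(design, rng),
                tacs=tacs,
                true_input=true_input,
                truths=truths,
            )
    return SimulatedStudy(design, schedule, sessions, pd.DataFrame(truth_rows))


def _abss_table(inp: InputFunction, design: StudyDesign, rng) -> BloodSampleTable:
    t = np.arange(0.0, 10.0 + 1e-9, 1.0 / 60.0)
    wb = np.interp(t, inp.time_min, inp.whole_blood_kbq_cc)
    noise = rng.normal(0.0, 1.0, t.size) * np.maximum(design.blood_noise_frac * wb, 1e-12)
    return BloodSampleTable(t, np.clip(wb + noise, 0.0, None), source="automatic")


def _manual_table(inp: InputFunction, design: StudyDesign, rng) -> BloodSampleTable:
    t = MANUAL_SAMPLE_TIMES_MIN
    wb = np.interp(t, inp.time_min, inp.whole_blood_kbq_cc)
    plasma = wb * design.plasma_to_blood_ratio
    wb_n = np.clip(wb * (1 + design.blood_noise_frac * rng.normal(size=t.size)), 1e-9, None)
    pl_n = np.clip(plasma * (1 + design.blood_noise_frac * rng.normal(size=t.size)), 1e-9, None)
    return BloodSampleTable(t, wb_n, pl_n, source="manual")


def _parent_table(design: StudyDesign, rng) -> ParentFractionTable:
    t = PARENT_SAMPLE_TIMES_MIN
    pf = simulate_parent_fraction(design.parent_params, t)
    pf_n = np.clip(pf + design.parent_noise_sd * rng.normal(size=t.size), 0.0, 1.0)
    return ParentFractionTable(t, pf_n)
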