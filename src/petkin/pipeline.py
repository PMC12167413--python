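"""End-to-end study orchestration.

``run_study`` drives one reproducible analysis run: obtain data (from a
simulation design or a data directory), build per-session input
functions, pick t* (whole-brain Max-Err policy or fixed), fit every
requested model to every regional TAC, and emit the report tables:

* ``fits.csv``            one row per subject/session/region/model
* ``vt_table.csv``        regional mean +/- SD of V_T per model
* ``model_comparison.csv``  AIC/MSC means and 2TC-vs-1TC winner counts
* ``agreement_<m>.csv``   graphical-vs-2TC Bland-Altman pairs
* ``test_retest.csv``     VAR and ICC per region per model
* ``time_stability.csv``  whole-brain V_T vs truncated duration
* ``manifest.json``       config, seed, version, t* actually used

Reruns with the same config are file-identical.
"""

from __future__ import annotations

import dataclasses
import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .core import REGION_ORDER, SubjectMeta, TimeActivityCurve
from .errors import InvalidArgumentError, PetkinError
from .compartment import fit_compartment
from .graphical import compare_to_2tc, fit_logan, fit_ma1, select_tstar
from .input_function import input_function_from_tables
from . import io as pio
from .reliability import (
    DEFAULT_DURATIONS_MIN,
    summarize_study,
    time_stability,
    var_by_duration,
)
from .simulate import SimulatedStudy, StudyDesign, simulate_study

__all__ = ["RunConfig", "RunResult", "run_study", "write_study_data", "load_study_data"]

_ALL_MODELS = ("1tc", "2tc", "logan", "ma1")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``design`` (simulate) or ``data_dir`` (load) must be
    set.  ``t_star_policy`` is either the string ``"auto"`` (estimate on
    the whole-brain TACs with the 10% Max-Err criterion, then fix
    globally) or a number of minutes.
    """

    design: StudyDesign | None = None
    data_dir: str | None = None
    models: tuple[str, ...] = _ALL_MODELS
    weights_mode: str = "uniform"
    vb_mode: str = "fit"
    t_star_policy: object = "auto"
    max_err_pct: float = 10.0
    parent_fit_window_min: float = 60.0
    durations_min: tuple[float, ...] = DEFAULT_DURATIONS_MIN
    time_stability_models: tuple[str, ...] = ("2tc", "logan", "ma1")
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.design is None) == (self.data_dir is None):
            raise InvalidArgumentError("exactly one of design / data_dir must be given")
        for m in self.models:
            if m not in _ALL_MODELS:
                raise InvalidArgumentError(f"unknown model {m!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        design = raw.pop("design", None)
        if design is not None:
            regions = design.pop("regions", None)
            if regions is not None:
                from .simulate import RegionKineticTruth

                design["regions"] = tuple(RegionKineticTruth(**r) for r in regions)
            design = StudyDesign(**design)
        for key in ("models", "time_stability_models", "durations_min"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(design=design, **raw)

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d, default=lambda o: getattr(o, "tolist", lambda: str(o))()))


@dataclass
class RunResult:
    fits: pd.DataFrame
    vt_table: pd.DataFrame
    test_retest: pd.DataFrame
    model_comparison: pd.DataFrame
    agreement: dict
    time_stability: pd.DataFrame
    t_star_min: float
    out_dir: Path | None = None


def write_study_data(study: SimulatedStudy, data_dir) -> None:
    """Materialise a simulated study in the package's file formats."""
    root = Path(data_dir)
    root.mkdir(parents=True, exist_ok=True)
    study.ground_truth.to_csv(root / "ground_truth.csv", index=False, float_format="%.17g")
    meta_rows = []
    for (subject, session), sess in sorted(study.sessions.items()):
        d = root / f"{subject}_{session}"
        d.mkdir(exist_ok=True)
        pio.write_tac_table(d / "tacs.csv", list(sess.tacs.values()))
        pio.write_blood_table(d / "blood.csv", [sess.abss, sess.manual])
        pio.write_parent_table(d / "parent.csv", sess.parent_samples)
        meta_rows.append(
            {
                "subject": subject,
                "session": session,
                "injected_activity_mbq": sess.meta.injected_activity_mbq,
                "body_weight_kg": sess.meta.body_weight_kg,
            }
        )
    pd.DataFrame(meta_rows).to_csv(root / "meta.csv", index=False, float_format="%.17g")


def load_study_data(data_dir) -> dict:
    """Load sessions written by :func:`write_study_data`.

    Returns ``{(subject, session): dict}`` with keys ``tacs`` (dict of
    TACs), ``abss``, ``manual``, ``parent``, ``meta``.
    """
    root = Path(data_dir)
    meta = pd.read_csv(root / "meta.csv")
    sessions = {}
    for _, row in meta.iterrows():
        d = root / f"{row.subject}_{row.session}"
        tacs = {t.region_label: t for t in pio.read_tac_table(d / "tacs.csv")}
        blood = {b.source: b for b in pio.read_blood_table(d / "blood.csv")}
        sessions[(row.subject, row.session)] = {
            "tacs": tacs,
            "abss": blood["automatic"],
            "manual": blood["manual"],
            "parent": pio.read_parent_table(d / "parent.csv"),
            "meta": SubjectMeta(
                row.subject, row.session, row.injected_activity_mbq, row.body_weight_kg
            ),
        }
    return sessions


def _whole_brain(tacs: dict) -> TimeActivityCurve:
    sched = next(iter(tacs.values())).schedule
    mean = np.mean([t.activity for t in tacs.values()], axis=0)
    return TimeActivityCurve(sched, mean, region_label="whole_brain")


def _snap_to_frame_start(t: float, schedule) -> float:
    starts = schedule.frame_start_min
    return float(starts[np.argmin(np.abs(starts - t))])


def run_study(config: RunConfig, out_dir=None) -> RunResult:
    """Execute the full pipeline; see the module docstring for outputs."""
    out = Path(out_dir) if out_dir is not None else None
    created = False
    if out is not None and not out.exists():
        out.mkdir(parents=True)
        created = True
    stage = "setup"
    try:
        stage = "data"
        if config.design is not None:
            design = dataclasses.replace(config.design, seed=config.seed)
            study = simulate_study(design)
            if out is not None:
                write_study_data(study, out / "data")
            sessions = {
                key: {
                    "tacs": sess.tacs,
                    "abss": sess.abss,
                    "manual": sess.manual,
                    "parent": sess.parent_samples,
                    "meta": sess.meta,
                }
                for key, sess in study.sessions.items()
            }
        else:
            sessions = load_study_data(config.data_dir)

        stage = "input-function"
        inputs = {
            key: input_function_from_tables(
                s["abss"], s["manual"], s["parent"], config.parent_fit_window_min
            )
            for key, s in sessions.items()
        }

        stage = "t-star"
        some_sched = next(iter(sessions.values()))["tacs"]
        if config.t_star_policy == "auto":
            estimates = []
            for key, s in sessions.items():
                wb = _whole_brain(s["tacs"])
                res = select_tstar(wb, inputs[key], "logan", config.max_err_pct)
                estimates.append(res.t_star_min)
            t_star = _snap_to_frame_start(float(np.median(estimates)), _whole_brain(some_sched).schedule)
        else:
            t_star = float(config.t_star_policy)

        stage = "fits"
        rows = []
        for key, s in sessions.items():
            subject, session = key
            inp = inputs[key]
            for region in sorted(s["tacs"], key=_region_key):
                tac = s["tacs"][region]
                for model in config.models:
                    if model in ("1tc", "2tc"):
                        f = fit_compartment(
                            tac, inp, model, config.weights_mode, config.vb_mode
                        )
                        rows.append(
                            dict(
                                subject=subject, session=session, region=region,
                                model=model, vt=f.vt, percent_se_vt=f.percent_se_vt,
                                aic=f.aic, msc=f.msc, K1=f.params.K1, k2=f.params.k2,
                                k3=f.params.k3, k4=f.params.k4, vB=f.params.vB,
                                converged=f.converged, t_star_min=np.nan,
                            )
                        )
                    else:
                        fitter = fit_logan if model == "logan" else fit_ma1
                        g = fitter(tac, inp, t_star)
                        rows.append(
                            dict(
                                subject=subject, session=session, region=region,
                                model=model, vt=g.vt, percent_se_vt=g.percent_se_vt,
                                aic=np.nan, msc=np.nan, K1=np.nan, k2=np.nan,
                                k3=np.nan, k4=np.nan, vB=np.nan,
                                converged=True, t_star_min=t_star,
                            )
                        )
        fits = pd.DataFrame(rows)

        stage = "model-comparison"
        model_cmp = _model_comparison(fits)

        stage = "agreement"
        agreement = {}
        if "2tc" in config.models:
            c2 = fits[fits.model == "2tc"][["subject", "session", "region", "vt"]]
            for gm in ("logan", "ma1"):
                if gm in config.models:
                    g = fits[fits.model == gm][["subject", "session", "region", "vt", "model"]]
                    g = g.rename(columns={"model": "method"})
                    agreement[gm] = compare_to_2tc(g, c2)

        stage = "reliability"
        vt_table, tr_table = summarize_study(fits)

        stage = "time-stability"
        ts_rows = []
        for key, s in sessions.items():
            wb = _whole_brain(s["tacs"])
            for model in config.time_stability_models:
                if model not in config.models:
                    continue
                kw = {}
                if model in ("1tc", "2tc"):
                    kw = dict(weights_mode=config.weights_mode, vb_mode=config.vb_mode)
                ts = time_stability(
                    wb, inputs[key], model, config.durations_min, t_star, **kw
                )
                for d, vt, ratio in zip(ts.durations_min, ts.vt, ts.ratio_to_full_pct):
                    ts_rows.append(
                        dict(
                            subject=key[0], session=key[1], model=model,
                            duration_min=d, vt=vt, ratio_to_full_pct=ratio,
                        )
                    )
        ts_table = pd.DataFrame(ts_rows)

        stage = "report"
        result = RunResult(
            fits=fits, vt_table=vt_table, test_retest=tr_table,
            model_comparison=model_cmp, agreement=agreement,
            time_stability=ts_table, t_star_min=t_star, out_dir=out,
        )
        if out is not None:
            _write_report(result, config, out)
        return result
    except Exception as exc:
        if out is not None and created:
            shutil.rmtree(out, ignore_errors=True)
        if isinstance(exc, PetkinError):
            raise
        raise PetkinError(f"pipeline stage {stage!r} failed: {exc}") from exc


def _region_key(region: str):
    try:
        return (0, REGION_ORDER.index(region))
    except ValueError:
        return (1, region)


def _model_comparison(fits: pd.DataFrame) -> pd.DataFrame:
    rows = []
    have = set(fits.model.unique())
    if not {"1tc", "2tc"} <= have:
        return pd.DataFrame(rows)
    for region, grp in fits.groupby("region", sort=False):
        g1 = grp[grp.model == "1tc"].set_index(["subject", "session"])
        g2 = grp[grp.model == "2tc"].set_index(["subject", "session"])
        common = g1.index.intersection(g2.index)
        rows.append(
            dict(
                region=region,
                aic_1tc_mean=g1.aic.mean(), aic_2tc_mean=g2.aic.mean(),
                msc_1tc_mean=g1.msc.mean(), msc_2tc_mean=g2.msc.mean(),
                n_2tc_aic_wins=int((g2.loc[common].aic.to_numpy() < g1.loc[common].aic.to_numpy()).sum()),
                n_pairs=len(common),
            )
        )
    return pd.DataFrame(rows)


def _write_report(result: RunResult, config: RunConfig, out: Path) -> None:
    fmt = dict(index=False, float_format="%.10g")
    result.fits.to_csv(out / "fits.csv", **fmt)
    result.vt_table.to_csv(out / "vt_table.csv", **fmt)
    result.model_comparison.to_csv(out / "model_comparison.csv", **fmt)
    result.test_retest.to_csv(out / "test_retest.csv", **fmt)
    result.time_stability.to_csv(out / "time_stability.csv", **fmt)
    for gm, summary in result.agreement.items():
        summary.pairs.to_csv(out / f"agreement_{gm}.csv", **fmt)
    manifest = {
        "config": config.to_jsonable(),
        "seed": config.seed,
        "t_star_min": result.t_star_min,
        "version": _version,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
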