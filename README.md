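# petkin

Plasma-input kinetic modelling and test–retest analysis for dynamic
brain PET, built around the quantification workflow used for novel
reversible radioligands (the bundled presets emulate a ¹¹C-labelled
mGlu4 tracer with rapid metabolism studied in six healthy volunteers,
two scans each).

## What it does

Given regional time–activity curves (TACs), arterial blood samples
(automatic sampler + manual draws) and measured parent fractions, the
package:

1. **builds the metabolite-corrected arterial input function** —
   cross-calibrated merge of automatic and manual whole-blood data, a
   piecewise-linear plasma/whole-blood ratio, and a constrained
   3-exponential parent-fraction fit anchored at pf(0)=1 and
   extrapolated to the end of the scan;
2. **fits compartment models** — one- and two-tissue models (1TC, 2TC)
   by weighted nonlinear least squares with an exact
   piecewise-linear-input convolution, reporting the total distribution
   volume `V_T = K1/k2` (1TC) or `V_T = (K1/k2)(1 + k3/k4)` (2TC), its
   delta-method %SE, AIC `n·ln(RSS/n) + 2p` and the model selection
   criterion (MSC);
3. **runs graphical analyses** — Logan (V_T = late-time slope of the
   normalized integral plot) and MA1 (multilinear form,
   `C_T(t) = −(V_T/b)∫Cp + (1/b)∫C_T`), with t\* chosen by the 10% Max
   Err criterion on a whole-brain TAC and then fixed globally;
4. **quantifies repeatability** — absolute test–retest variability
   `VAR = 200·|V_T¹ − V_T²|/(V_T¹ + V_T²)`, the one-way
   random-effects ICC `(MS_B − MS_W)/(MS_B + (k−1)·MS_W)` with
   F-based 95% CI, and V_T time-stability under scan truncation;
5. **simulates complete studies** with known ground truth — Feng-type
   tri-exponential plasma input, tri-exponential parent fraction
   (10–20% at 20 min), 2TC tissue kinetics with the regional V_T rank
   order pons > thalamus ≈ putamen > frontal cortex > cerebellum, and
   log-normal between-subject / test–retest variance components. The
   simulator integrates the kinetic ODEs directly, while the fitters
   use closed-form convolution, so each route validates the other.

## Worked example

```python
import pandas as pd
from petkin import (
    StudyDesign, simulate_study, input_function_from_tables,
    fit_compartment, fit_logan, summarize_study,
)

study = simulate_study(StudyDesign(n_subjects=6, seed=1))
rows = []
for (subject, session), s in study.sessions.items():
    inp = input_function_from_tables(s.abss, s.manual, s.parent_samples,
                                     fit_window_end_min=60.0)
    for region, tac in s.tacs.items():
        fit = fit_compartment(tac, inp, model="2tc")
        rows.append(dict(subject=subject, session=session, region=region,
                         model="2tc", vt=fit.vt))

vt_table, tr_table = summarize_study(pd.DataFrame(rows))
print(tr_table[["region", "var_mean_pct", "icc"]].round(2).to_string(index=False))
```

prints

```
        region  var_mean_pct  icc
          pons          5.94 0.96
      thalamus          5.91 0.97
       putamen          5.89 0.96
frontal_cortex          3.49 0.94
    cerebellum          3.49 0.99
```

i.e. with the default variance components (between-subject CV 20%,
test–retest CV 3% per micro-parameter, count-statistics frame noise)
the fitted 2TC V_T repeats to 3–6% absolute variability with
ICC ≥ 0.94 in every region — the regime reported for well-behaved
reversible tracers without a reference region.

The same pipeline is available from the shell:

```bash
petkin simulate --out data/ --seed 1
petkin run --config run.yaml --out results/
```

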