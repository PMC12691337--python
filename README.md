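# gaskinetics

Nonlinear kinetic analysis of **in vitro rumen cumulative gas
production** — the standard bench assay in ruminant nutrition where a
feed substrate is incubated in buffered rumen fluid and the fermentation
gas it releases is logged by pressure sensors, here every 5 minutes over
24 hours. The shape of the cumulative curve P(t) (mL gas per 100 mg
incubated dry matter) carries the degradation kinetics of the feed.

The package is built around three questions, the workflow used to
evaluate elephant-grass silages with increasing inclusion of dehydrated
cashew pseudo-fruit (0/10/20/30 %):

1. **Which model family describes the curve best?** Five classical
   families are fitted — Gompertz `A·exp(−B·exp(−Ct))`,
   Ørskov–McDonald `A + B(1 − exp(−Ct))`, Brody `A(1 − B·exp(−Ct))`,
   Richards `A(1 − B·exp(−Ct))^D`, and the dual-pool logistic
   `A/(1+exp(2−4B(t−C))) + D/(1+exp(2−4E(t−C)))` — by modified
   Gauss–Newton or Levenberg–Marquardt least squares, then ranked by
   AIC, R² of predicted-on-observed, Lin's concordance correlation
   (CCC), and MSPE with its bias decomposition, with AIC **evidence
   ratios** exp(ΔAIC/2) and paired-MSPE accuracy tests between models.
2. **Do treatments share one degradation curve?** A full model (separate
   fits per inclusion level) is compared with a reduced model (one
   global fit) through the extra-sum-of-squares F test, pairwise across
   all levels.
3. **Can the whole pipeline be exercised without the lab?** A synthetic
   generator reproduces the incubation design (replicate flasks, blank
   flasks, 5-min readings) from known Richards truths, with monotone
   cumulative noise and blank correction, so every stage is testable
   end to end.

## Worked example

```python
import numpy as np
from gaskinetics import (ExperimentConfig, blank_correct, fit,
                         generate_experiment, rank_models)
from gaskinetics.pipeline import average_curve

table = generate_experiment(ExperimentConfig(seed=1))   # 27 flasks x 289 readings
curves = blank_correct(table)                           # -> mL/100 mg DM
avg = average_curve(curves)
fits = [fit(avg, m) for m in ("gompertz", "brody", "richards")]
adequacy, comparison = rank_models(fits, avg)
print(adequacy[["aic", "r2", "ccc", "mspe"]].round(4))
print("best:", comparison.reference_model_id)
```

prints

```
                aic      r2     ccc    mspe
model
gompertz  -1666.2989  0.9988  0.9994  0.0030
brody     -1551.2643  0.9982  0.9991  0.0045
richards  -3317.1795  1.0000  1.0000  0.0000
best: richards
```

The Richards family wins decisively (lowest AIC; on synthetic data
generated from Richards truths its evidence ratio advantage saturates),
and the fitted per-treatment parameters show what the inclusion levels
do: the asymptote A rises from ≈4.9 to ≈6.2 mL/100 mg DM and the
fractional rate C from ≈0.10 to ≈0.17 h⁻¹ between 0 % and 30 %
inclusion, while the shape term B drops below 1 — fermentation starts
without a lag. All six pairwise identity tests reject (p < 0.0001): no
single global curve describes the four silages.

The same workflow is scripted as a narrative under `analysis/`
(`01_simulate.py` → `04_identity_tests.py`, plus
`05_recover_printed_curves.py`, each writing tables to `results/`) and
as a CLI:

```bash
gaskinetics simulate --seed 1 --out raw_gas.csv
gaskinetics evaluate raw_gas.csv
gaskinetics compare raw_gas.csv --model richards
gaskinetics run --seed 1 --out results/
```

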