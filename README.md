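# ligaseflux

Quantifying ubiquitin-ligase activity from degron-reporter fluorescence
dynamics in single cells.

E3 ubiquitin ligases of the SCF family (Skp1–Cullin1–F-box; the β-TrCP
adapter is the motivating case) are read out in live cells with a
fluorescent reporter carrying the ligase's degron: the reporter is
transcribed from a constitutive promoter and destroyed by the ligase, so
its level R(t) obeys

    dR/dt = s − k(t)·R

with constant synthesis rate *s* and a degradation rate constant *k*
that tracks ligase activity through the cell cycle. The instantaneous
degradation flux

    A(t) = s − dR/dt  ( = k·R )

is the relative ligase activity. `ligaseflux` implements the full
computational route from time-lapse movies (or plate reads) to A(t),
for cell biologists benchmarking degron reporters and screeners
analyzing luminescent reporter assays:

- **`ligaseflux.synth`** — synthetic benchmark data with known ground
  truth: cell-cycle phase schedules, reporter/Geminin traces from the
  exact piecewise-analytic ODE solution, rendered multichannel image
  series with illumination bias, 1536-well screening plates, and paired
  live/fixed single-cell datasets.
- **`ligaseflux.imaging`** — empirical illumination-bias estimation and
  flattening, global background subtraction, nuclear segmentation
  (Otsu + watershed splitting), greedy mutual-nearest-neighbour tracking
  with division detection, and median-nuclear-intensity trace extraction.
- **`ligaseflux.kinetics`** — Geminin-based phase annotation, mitotic
  artifact masking, synthesis-rate estimation from the post-MLN-4924
  accumulation slope, activity A = s − dR/dt, cycloheximide-chase
  half-life fitting, and computational alignment of traces to mitosis.
- **`ligaseflux.screen`** — per-plate percent-activity normalization
  against neutral/negative control medians, strict >50% hit calling,
  11-point 1:3 titration four-parameter-logistic IC50 fitting, and
  counter-screen selectivity filtering.
- **`ligaseflux.popstats`** — live-to-fixed cell matching,
  activity-vs-protein correlation with bootstrap CIs, between-population
  activity folds, and IC50 fold shifts.

## Worked example

Recover a cycloheximide-chase half-life and a synthesis rate from
simulated single cells:

```python
import numpy as np
from ligaseflux.synth import simulate_phase_schedule, simulate_reporter_trace
from ligaseflux.types import KineticParams, Perturbation
from ligaseflux.kinetics import estimate_half_life, estimate_synthesis_rate, compute_activity

sched = simulate_phase_schedule(1, {"G0": 1.0}, duration=8.0, seed=0)[0]
params = KineticParams(s=0.0, k_by_phase={"G0": 0.2521}, noise_cv=0.05, R0=100.0)
trace = simulate_reporter_trace(sched, params, [Perturbation.chx(0.0)], seed=1)
fit = estimate_half_life(trace)
print(f"t1/2 = {fit.t_half:.3f} h (r^2 = {fit.r_squared:.4f})")

mln_sched = simulate_phase_schedule(1, {"G0": 1.0}, duration=12.0, seed=0)[0]
mln_params = KineticParams(s=10.0, k_by_phase={"G0": 0.25}, noise_cv=0.05)
mln = [simulate_reporter_trace(mln_sched, mln_params, [Perturbation.mln4924(2.0)], seed=i)
       for i in range(50)]
s_est, _, _ = estimate_synthesis_rate(mln)
print(f"s = {s_est:.3f} a.u./h")
```

Output:

```
t1/2 = 2.725 h (r^2 = 0.9941)
s = 10.014 a.u./h
```

The fitted half-life matches ln 2 / 0.2521 = 2.75 h — the G1-phase
reporter half-life — and the synthesis-rate estimate recovers the
generating s = 10 a.u./h from the post-MLN accumulation slopes. With
`k = 0.0770 /h` the same chase yields the 9 h S/G2-phase half-life.

A thin CLI covers the common steps:

```
ligaseflux simulate traces --out traces.csv --n-cells 50 --seed 1
ligaseflux simulate plate --out plate.csv --seed 1
ligaseflux normalize plate.csv --out pa.csv
ligaseflux hits pa.csv --threshold 50
```

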