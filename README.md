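# t1sim

Simulation and analysis toolkit for **3D free-breathing saturation-recovery
myocardial T1 mapping** at 3 T.

Quantitative T1 maps of the whole heart can be acquired without
breath-holding by collecting three ECG-triggered, navigator-gated,
volume-interleaved T1-weighted volumes: two saturation-prepared volumes with
delays T_SAT1 = T_MAX/2 and T_SAT2 = T_MAX (T_MAX = 80% of the R-R
interval), and one unprepared *equilibrium* volume acquired only after ≥ 6 s
of recovery. T1 is then estimated pixel-wise with the two-parameter model

    S(T_SAT) = A (1 − exp(−T_SAT / T1)),

treating the equilibrium volume as S(∞) = A. Because the equilibrium
recovery can only be scheduled in whole heartbeats and is finite, the
estimate carries a small, systematic, heart-rate-dependent negative bias —
quantifying that bias (and its spread under heart-rate variability) is the
core purpose of this package. It is aimed at sequence developers and
quantitative-MRI researchers who want to reason about saturation-recovery
protocol timing without scanner time.

## What's inside

| module | contents |
|---|---|
| `t1sim.bloch` | closed-form longitudinal magnetization primitives (saturation, relaxation, ideally spoiled SPGR readout train) |
| `t1sim.sequence` | beat-by-beat simulator of the interleaved 3-volume acquisition with heart-rate variability, navigator gating, and real-time recovery-beat scheduling |
| `t1sim.montecarlo` | the accuracy/precision study: T1 error vs recovery time, and the Monte Carlo surface over (T1, heart rate) |
| `t1sim.fitting` | nonlinear least-squares engines for the 2-parameter saturation-recovery, 3-parameter inversion-recovery, and saturation-efficiency models; pixel-wise map fitting |
| `t1sim.phantom` | digital vial and short-axis cardiac phantoms with known ground truth |
| `t1sim.analysis` | ROI statistics, AHA 16-segment labeling, bull's-eye tables, regression/Bland–Altman/paired-t method comparison |
| `t1sim.io` | NIfTI-1 volumes and T1 maps with JSON delay sidecars |

## Worked example

```python
import numpy as np
from t1sim import (TissueSpecies, SequenceParams, HeartRateProcess,
                   NavigatorModel, RFReadoutParams, simulate_acquisition)
from t1sim.montecarlo import MCStudyConfig, run_mc_study

# one acquisition cycle for myocardium at a fixed 60 bpm, ideal readout
seq = SequenceParams(rf=RFReadoutParams(n_readouts=0))
sim = simulate_acquisition(
    seq,
    HeartRateProcess(mean_bpm=60, sd_bpm=0, model="fixed"),
    NavigatorModel(acceptance_prob=1.0),
    TissueSpecies(t1=1550),
)
print(sim.to_dataframe()[["volume_id", "t_sat_ms", "recovery_ms", "signal"]])
#   volume_id  t_sat_ms  recovery_ms    signal
# 0      IMG1     400.0          NaN  0.227455
# 1      IMG2     800.0          NaN  0.403174
# 2      IMG3       NaN       6000.0  0.979162

# Monte Carlo error for this species at the highest heart rate
cfg = MCStudyConfig(t1_grid_ms=[1550.0], hr_grid_bpm=[120.0],
                    n_reps=1000, seed=1)
print(run_mc_study(cfg).table.round(3))
#    t1_ms  hr_bpm  mean_rel_err_pct  sd_rel_err_pct  mean_recovery_frac
# 0   1550   120.0            -1.688           0.088               0.985
```

Reading the numbers: at 60 bpm the saturation delays are 400 and 800 ms and
the equilibrium volume is read after exactly six 1000 ms beats, by which
time a T1 = 1550 ms species has recovered to 97.9% of equilibrium — so the
anchor is slightly deflated and the fitted T1 is biased low. At 120 bpm with
5 bpm beat-to-beat variability the mean error is −1.7% with a spread of
under 0.1%: the measurement is heart-rate robust because saturation resets
the magnetization history every cycle.

The same machinery is scriptable from the shell: `t1sim simulate`,
`t1sim montecarlo`, `t1sim fit`, `t1sim phantom`, `t1sim analyze`
(see `t1sim --help`).

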