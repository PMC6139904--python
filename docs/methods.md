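# Methods

## The measurement being modeled

`t1sim` models a 3D free-breathing myocardial T1-mapping acquisition at 3 T
that estimates T1 from three co-registered, differently T1-weighted volumes:

* **IMG1** and **IMG2** are saturation-prepared. A composite saturation pulse
  (efficiency η, ideally 1) nulls the longitudinal magnetization; the image
  readout follows after a saturation delay T_SAT. The delays follow the
  maximal-delay rule: T_MAX is 80% of the current R-R interval, and
  T_SAT1 = T_MAX/2, T_SAT2 = T_MAX. Because the saturation pulse resets the
  magnetization history every cycle, the sampled recovery curve is
  insensitive to heart-rate variation.
* **IMG3** is acquired without preparation after a long recovery and anchors
  the equilibrium signal A of the fit. For native T1 a minimum recovery of
  6 s is targeted (3 s post-contrast, where T1 ≈ 800 ms).

Pixel-wise T1 comes from nonlinear least squares with the two-parameter
saturation-recovery model

    S(T_SAT) = A (1 − exp(−T_SAT / T1)),

with IMG3 treated as the equilibrium sample S(∞) = A. Two further models are
provided: the three-parameter inversion-recovery model
`S = A + B exp(−T_INV / T1)` (the reference standard when paired with a
spin-echo readout and long TR) and the saturation-efficiency model
`S = A (1 − η exp(−T_SAT / T1))` used to measure η itself.

## Magnetization model

All signal synthesis is composed from closed-form longitudinal-evolution
primitives (`t1sim.bloch`): saturation scales Mz by (1 − η); free recovery is
`m0 + (mz − m0) exp(−t/T1)`; the SPGR readout train uses the ideal-spoiling
recursion (each pulse samples `mz sin α` transverse signal, projects the
longitudinal component by `cos α`, and relaxes one TR), evaluated in closed
form because the recursion is linear. Transverse coherences, off-resonance,
B0/B1+ inhomogeneity, slice profiles and fat are outside the model; T2 is
carried on tissue species only as phantom metadata. The k-space center is
read at the first pulse (centric profile order, the convention for
saturation-recovery imaging, so T_SAT is exactly saturation→first readout);
linear ordering (middle pulse) is available as an option.

`n_readouts = 0` selects an idealized readout used throughout the simulation
studies: the sampled signal is Mz itself and the train is assumed to consume
the remaining longitudinal magnetization. This mirrors the approximation
that Mz is negligible after a 33-pulse readout, and makes the recovery of
IMG3 start from zero — the assumption under which the accuracy study is
defined. With the full SPGR train enabled, the small residual magnetization
and the ~76 ms train duration are tracked explicitly instead.

## Scheduling

Heartbeats are modeled as i.i.d. per-beat draws, Gaussian in bpm space
(default SD 5 bpm), truncated to [20, 220] bpm. Respiratory navigator
physics is out of scope; gating is an i.i.d. Bernoulli acceptance applied to
the IMG1/IMG2 shot pair as a unit and to each IMG3 readout opportunity
independently. A rejected pair is re-attempted next beat with a fresh
saturation; a rejected IMG3 readout simply accrues another recovery beat, so
rejections can only lengthen the realized recovery.

Two scheduling rules for the equilibrium volume are implemented, and they
differ deliberately:

* **Real-time rule** (`simulate_acquisition`): after the IMG2 readout of the
  cycle, beats are skipped until the elapsed recovery at the next readout
  opportunity meets the target. This guarantees `recovery ≥ target` under
  any heart-rate trajectory and realizes exactly `ceil(target/RR)·RR` at a
  fixed heart rate — the behavior of the running scanner, whose in vivo
  minimum recoveries sit just above the 6 s floor.
* **Prescribed-mean rule** (`run_mc_study`, default): the idle-beat count
  `n = ceil(target / RR_mean)` is fixed from the prescribed mean heart rate;
  the n idle beats are fully skipped and IMG3 is acquired on the following
  beat at the same cardiac phase as IMG2, so `n + 1` realized beat intervals
  elapse readout-to-readout. This is the configuration of the accuracy
  study: its systematic overshoot (≈ one R-R interval) shrinks as heart rate
  rises, which is why the T1 error *grows* with heart rate in the Monte
  Carlo results while remaining bounded. The deliberate mismatch between the
  two rules brackets the behavior of the real sequence.

The recovery clock starts at the end of the IMG2 readout; with the idealized
readout, readout events are instants at the diastolic trigger point
(`tmax_fraction` of the way into the beat), so fixed-heart-rate recoveries
are exact beat multiples.

## The accuracy/precision study

For each (T1, mean HR) cell and repetition, noiseless signals are
synthesized at the rule delays with ideal saturation, the IMG3 sample is
deflated to the realized recovery fraction `1 − exp(−t_rec/T1)`, and the
2-parameter model is fitted through the production fitting engine with IMG3
treated as equilibrium. The signed relative error `100·(T1_fit − T1)/T1` is
aggregated per cell (mean, SD with n−1). The error is systematic and
negative: the deflated anchor underestimates A, and the fit underestimates
T1. Because the saturation pulse timing is slaved to the readout, T_SAT
values are exact regardless of heart-rate fluctuation; only the IMG3
recovery inherits the variability.

Default grid: T1 ∈ {500, 750, 1000, 1250, 1550, 1750} ms (1550 ms = typical
native myocardium at 3 T), mean HR 40–120 bpm in 10 bpm steps, per-beat SD
5 bpm, 6 s target. The library default is 2000 repetitions per cell; the
acceptance script uses 1000, at which the per-cell mean error carries a
Monte Carlo standard error below 0.03% and the SD estimate is stable to a
few percent relative — ample for the sub-percent quantities reported.

## Fitting engine

Bounded trust-region least squares (`scipy.optimize.least_squares`) with
analytic Jacobians. Initialization: A₀ = max signal, T1₀ = 1000 ms,
B₀ = −2A₀ (ir3), η₀ = 0.95. Bounds: T1 ∈ [1, 10000] ms, A > 0,
η ∈ [0, 1.05] (slightly above 1 so a true efficiency of ~1 is not biased by
the boundary). Convergence: parameter/cost tolerances 1e-10, cap 500
evaluations. Constant (including all-zero) series return a flagged
non-converged result. Magnitude data are fitted as-is for the saturation
models; the inversion model offers optional polarity restoration (every
early-negation split is tried, lowest residual wins) for magnitude IR data.

## Digital phantoms

The vial phantom is 12 non-overlapping disks on a circle with T1 log-spaced
over 500–1800 ms (T2 30–80 ms as metadata), emulating agarose/Gd-DTPA vials
spanning myocardial relaxation times at 3 T. The cardiac phantom is a stack
of myocardial annuli (T1 1550 ms) around a blood pool (T1 2100 ms) with
slices split evenly into base/mid/apex slabs. Per-voxel signals are painted
from the sequence simulation for each distinct species; noise is additive
i.i.d. Gaussian per weighted volume with SD expressed as a fraction of the
equilibrium signal A (Rician magnitude noise behind a flag; the 3D
acquisition operates at high SNR where the Gaussian approximation holds).
Default noise levels are calibration choices, not physics: 0.2% of A for
vials (reproducing the sub-percent map CV of scanned gel vials) and 0.65%
of A for the cardiac phantom (yielding ≈2% septal CV on the fitted map, the
precision scale reported for this family of sequences in vivo). Geometry is
seed-independent; noise is owned by the spec seed, so identical seeds give
bit-identical volumes.

What the phantoms do **not** emulate: coil sensitivity, motion and
misregistration, partial-volume ramps (labels are nearest-neighbor), fat,
field inhomogeneity. Passing phantom tests therefore demonstrates the
correctness of the estimation pipeline and its finite-recovery bias — not
robustness to those in vivo confounders.

## Segment analysis

AHA left-ventricular segmentation is applied slice-wise to short-axis masks:
six 60° segments per basal and mid slice, four 90° per apical slice,
measured from the anterior RV insertion angle, clockwise as viewed from the
apex (configurable). Only the 16 short-axis segments are scored; the apical
cap (segment 17) has no short-axis extent and is intentionally omitted.
ROI statistics use the n−1 SD and CV = 100·SD/mean; method comparison
reports OLS regression of test on reference, Bland–Altman bias with
bias ± 1.96·SD limits of agreement, and a two-tailed paired t-test.

## Numerical and design notes

* `ceil` computations on beat counts subtract 1e-12 before rounding so exact
  multiples (6000 ms at RR 1000 ms) do not gain a spurious beat.
* `relax` short-circuits t = 0 to return the input bit-exactly.
* The explicit T_SAT override (`SequenceParams.t_sat_override`) exists
  because deployed protocols sometimes report delays a few ms off the rule
  values (hardware event timing); the rule is never hard-coded against it.
* Equilibrium samples use an infinite-delay marker rather than a large
  finite delay, so the model returns A exactly for them.
* The vial end-to-end regression slope of ~0.95 on noiseless data is the
  deterministic finite-recovery bias (longer T1 → larger negative error),
  not a noise effect.

## Problem sizes

Module tests use reduced grids (hundreds of repetitions, ≤64² in-plane
phantoms); the acceptance script runs the full 6 × 9 grid at 1000
repetitions per cell (54,000 fits, about 1–2 minutes on one CPU). These
sizes keep the Monte Carlo standard errors comfortably below the margins of
the quantities being checked.

## Known limitations

* No SNR-driven (noise-propagation) precision theory; precision statements
  come from the calibrated phantom noise model only.
* k-space reconstruction, navigator physics, fat suppression and shimming
  are out of scope; their effects are absorbed into scalar knobs
  (η, acceptance probability) or ignored.
* The inversion-recovery reference assumes perfect inversion (B = −2A) when
  generating reference data; the fit itself leaves B free.
* ECV computation and comparisons against single-shot 2D protocols on real
  subjects are out of scope.
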