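"""ECG-triggered, navigator-gated, volume-interleaved acquisition simulator.

The modeled sequence acquires three differently T1-weighted volumes per
interleave cycle:

* ``IMG1`` — saturation-prepared, delay T_SAT1 = T_MAX / 2,
* ``IMG2`` — saturation-prepared, delay T_SAT2 = T_MAX,
* ``IMG3`` — unprepared equilibrium anchor, acquired only after the
  longitudinal magnetization has recovered for at least ``target_recovery``
  (6 s by default for native T1; 3 s is typical post-contrast),

where T_MAX is a fixed fraction (default 80%) of the current R-R interval.
Each shot is triggered to diastole, so the readout (k-space center) sits at
``tmax_fraction * RR`` after the R-wave and the saturation pulse is played
T_SAT earlier in the same beat.

Scheduling of the equilibrium volume follows the real-time rule used on the
scanner: after the IMG2 readout of the cycle, heartbeats are skipped until
the *elapsed* recovery at the next readout opportunity meets the target, so
the minimum recovery is guaranteed under any heart-rate trajectory.  At a
fixed heart rate this realizes exactly ``ceil(target / RR) * RR`` of
recovery.  Respiratory navigator acceptance is modeled as an i.i.d.
Bernoulli gate: a rejected IMG1/IMG2 pair is re-attempted on the next beat
with a fresh saturation, and a rejected IMG3 readout simply accrues one more
recovery beat.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .bloch import RFReadoutParams, TissueSpecies, relax, saturate, spgr_train

__all__ = [
    "SequenceParams",
    "HeartRateProcess",
    "NavigatorModel",
    "ShotLog",
    "SimulationResult",
    "ConfigurationError",
    "ScanAbortedError",
    "compute_tmax",
    "compute_idle_beats",
    "simulate_acquisition",
    "available_magnetization_surface",
    "SHOTLOG_COLUMNS",
]

SHOTLOG_COLUMNS = (
    "shot_index",
    "volume_id",
    "t_sat_ms",
    "recovery_ms",
    "rr_ms",
    "accepted",
    "signal",
    "mz_pre_readout",
)


class ConfigurationError(ValueError):
    """Raised when the requested timing cannot be realized."""


class ScanAbortedError(RuntimeError):
    """Raised when the simulated scan exceeds its maximum beat budget."""


@dataclass
class SequenceParams:
    """Timing and RF parameters of the 3-volume acquisition."""

    tmax_fraction: float = 0.8
    target_recovery_ms: float = 6000.0
    n_shots: int = 1
    rf: RFReadoutParams = field(default_factory=RFReadoutParams)
    sat_efficiency: float = 1.0
    trigger_delay_ms: float = 0.0
    #: optional explicit (T_SAT1, T_SAT2) in ms overriding the T_MAX rule
    t_sat_override: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        if not 0 < self.tmax_fraction <= 1:
            raise ValueError(f"tmax_fraction must be in (0, 1], got {self.tmax_fraction}")
        if not self.target_recovery_ms > 0:
            raise ValueError("target_recovery_ms must be > 0")
        if self.n_shots < 1:
            raise ValueError("n_shots must be >= 1")
        if not 0 <= self.sat_efficiency <= 1:
            raise ValueError("sat_efficiency must be in [0, 1]")

    def t_sats(self, rr_ms: float) -> Tuple[float, float]:
        """(T_SAT1, T_SAT2) for the given R-R interval."""
        if self.t_sat_override is not None:
            return self.t_sat_override
        tmax = compute_tmax(rr_ms, self.tmax_fraction)
        return tmax / 2.0, tmax


@dataclass
class HeartRateProcess:
    """Per-beat heart-rate model: fixed, or i.i.d. Gaussian in bpm space.

    Draws are truncated to [20, 220] bpm before conversion to R-R intervals.
    """

    mean_bpm: float
    sd_bpm: float = 5.0
    model: str = "gaussian_per_beat"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.mean_bpm > 0:
            raise ValueError("mean_bpm must be > 0")
        if self.sd_bpm < 0:
            raise ValueError("sd_bpm must be >= 0")
        if self.model not in ("fixed", "gaussian_per_beat"):
            raise ValueError(f"unknown heart-rate model {self.model!r}")

    @property
    def mean_rr_ms(self) -> float:
        return 60000.0 / self.mean_bpm

    def draw_rr(self, rng: np.random.Generator) -> float:
        """One realized R-R interval in ms."""
        if self.model == "fixed" or self.sd_bpm == 0:
            return self.mean_rr_ms
        bpm = float(np.clip(rng.normal(self.mean_bpm, self.sd_bpm), 20.0, 220.0))
        return 60000.0 / bpm


@dataclass
class NavigatorModel:
    """Respiratory gating as an i.i.d. Bernoulli acceptance per gate check."""

    acceptance_prob: float = 1.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0 <= self.acceptance_prob <= 1:
            raise ValueError("acceptance_prob must be in [0, 1]")

    def accept(self, rng: np.random.Generator) -> bool:
        if self.acceptance_prob >= 1.0:
            return True
        return bool(rng.random() < self.acceptance_prob)


@dataclass
class ShotLog:
    """Per-shot record (one row of the shot table)."""

    shot_index: int
    volume_id: str
    t_sat_ms: float  # nan for IMG3
    recovery_ms: float  # nan for IMG1/IMG2
    rr_ms: float
    accepted: bool
    signal: float  # nan for rejected shots
    mz_pre_readout: float


@dataclass
class SimulationResult:
    shots: List[ShotLog]
    species: TissueSpecies
    seq: SequenceParams

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            (
                s.shot_index,
                s.volume_id,
                s.t_sat_ms,
                s.recovery_ms,
                s.rr_ms,
                s.accepted,
                s.signal,
                s.mz_pre_readout,
            )
            for s in self.shots
        ]
        return pd.DataFrame(rows, columns=list(SHOTLOG_COLUMNS))

    def mean_signal(self, volume_id: str) -> float:
        vals = [s.signal for s in self.shots if s.volume_id == volume_id and s.accepted]
        return float(np.mean(vals)) if vals else float("nan")

    @property
    def mean_signals(self) -> Tuple[float, float, float]:
        """(S1, S2, S3) averaged over accepted shots."""
        return (
            self.mean_signal("IMG1"),
            self.mean_signal("IMG2"),
            self.mean_signal("IMG3"),
        )


def compute_tmax(rr_ms: float, tmax_fraction: float = 0.8) -> float:
    """Maximal usable saturation delay: a fixed fraction of the R-R interval."""
    if not rr_ms > 0:
        raise ValueError("rr_ms must be > 0")
    return rr_ms * tmax_fraction


def compute_idle_beats(rr_estimate_ms: float, target_recovery_ms: float) -> int:
    """Smallest integer n of heartbeats with ``n * RR >= target_recovery``."""
    if not rr_estimate_ms > 0 or not target_recovery_ms > 0:
        raise ValueError("rr_estimate_ms and target_recovery_ms must be > 0")
    # guard against float noise on exact multiples (6000 / 1000 -> 6, not 7)
    return int(math.ceil(target_recovery_ms / rr_estimate_ms - 1e-12))


def simulate_acquisition(
    seq: SequenceParams,
    hr: HeartRateProcess,
    nav: NavigatorModel,
    species: TissueSpecies,
    max_beats: Optional[int] = None,
) -> SimulationResult:
    """Simulate the full interleaved 3-volume acquisition for one species.

    Each cycle acquires one shot of IMG1, IMG2 and IMG3 in that order;
    ``seq.n_shots`` cycles are run.  All magnetization bookkeeping is
    delegated to the closed-form primitives in :mod:`t1sim.bloch`, with
    events (saturation pulses, readout trains) placed on the realized
    beat-by-beat timeline.

    Raises :class:`ScanAbortedError` when the beat budget is exhausted
    (e.g. navigator acceptance 0), and :class:`ConfigurationError` when a
    saturation delay does not fit between the previous readout and its
    own readout (only possible with an explicit ``t_sat_override``).
    """
    if max_beats is None:
        # generous default: worst-case beats per cycle at low acceptance
        per_cycle = 4 + seq.target_recovery_ms / 200.0
        accept = max(nav.acceptance_prob, 1e-3)
        max_beats = int(seq.n_shots * per_cycle / accept * 50) + 200

    rng_hr = np.random.default_rng(hr.seed)
    rng_nav = np.random.default_rng(nav.seed)

    shots: List[ShotLog] = []
    mz = species.m0
    t_now = 0.0  # time of the last processed magnetization event
    beat_start = 0.0
    shot_index = 0
    cycles_done = 0
    pending = "IMG1"  # next volume to attempt
    rec_start = float("nan")  # recovery clock origin (end of IMG2 readout)
    train_ms = seq.rf.duration_ms

    beats = 0
    while cycles_done < seq.n_shots:
        beats += 1
        if beats > max_beats:
            raise ScanAbortedError(
                f"scan did not complete within {max_beats} heartbeats "
                f"(navigator acceptance {nav.acceptance_prob}); "
                f"{cycles_done}/{seq.n_shots} cycles done"
            )
        rr = hr.draw_rr(rng_hr)
        readout_t = beat_start + seq.tmax_fraction * rr + seq.trigger_delay_ms
        t_sat1, t_sat2 = seq.t_sats(rr)

        if pending in ("IMG1", "IMG2"):
            t_sat = t_sat1 if pending == "IMG1" else t_sat2
            sat_t = readout_t - t_sat
            if sat_t < t_now - 1e-9:
                raise ConfigurationError(
                    f"shot {shot_index} ({pending}): T_SAT = {t_sat:.1f} ms does "
                    f"not fit in the available window before the readout at "
                    f"t = {readout_t:.1f} ms (previous event at {t_now:.1f} ms)"
                )
            mz = relax(mz, species, sat_t - t_now)
            mz = saturate(mz, seq.sat_efficiency)
            mz = relax(mz, species, t_sat)
            t_now = readout_t

            # one navigator decision gates the IMG1/IMG2 pair as a unit
            accepted = nav.accept(rng_nav) if pending == "IMG1" else True
            if accepted:
                mz_pre = mz
                signal, mz = spgr_train(mz, species, seq.rf)
                t_now = readout_t + train_ms
                shots.append(
                    ShotLog(shot_index, pending, t_sat, float("nan"), rr, True,
                            signal, mz_pre)
                )
                if pending == "IMG2":
                    rec_start = t_now  # recovery clock: end of IMG2 readout
                    pending = "IMG3"
                else:
                    pending = "IMG2"
            else:
                shots.append(
                    ShotLog(shot_index, pending, t_sat, float("nan"), rr, False,
                            float("nan"), mz)
                )
            shot_index += 1

        else:  # IMG3: wait until the elapsed recovery meets the target
            elapsed = readout_t - rec_start
            if elapsed + 1e-9 < seq.target_recovery_ms:
                beat_start += rr
                continue
            if nav.accept(rng_nav):
                mz = relax(mz, species, readout_t - t_now)
                mz_pre = mz
                signal, mz = spgr_train(mz, species, seq.rf)
                t_now = readout_t + train_ms
                shots.append(
                    ShotLog(shot_index, "IMG3", float("nan"), elapsed, rr, True,
                            signal, mz_pre)
                )
                cycles_done += 1
                pending = "IMG1"
            else:
                shots.append(
                    ShotLog(shot_index, "IMG3", float("nan"), elapsed, rr, False,
                            float("nan"), relax(mz, species, readout_t - t_now))
                )
            shot_index += 1

        beat_start += rr

    return SimulationResult(shots=shots, species=species, seq=seq)


def available_magnetization_surface(
    t1_grid: Sequence[float],
    hr_grid: Sequence[float],
    seq: Optional[SequenceParams] = None,
) -> pd.DataFrame:
    """Deterministic (T1, HR) table of normalized signals S1, S2, S3.

    S1 and S2 are the saturation-recovery fractions at the rule delays
    T_MAX/2 and T_MAX; S3 is the recovery fraction from zero magnetization
    over the realized fixed-heart-rate recovery ``ceil(target / RR) * RR``.
    Signals are per unit M0 with an idealized (non-perturbing) readout.
    """
    if seq is None:
        seq = SequenceParams()
    if len(t1_grid) == 0 or len(hr_grid) == 0:
        raise ValueError("t1_grid and hr_grid must be non-empty")
    rows = []
    for hr_bpm in hr_grid:
        rr = 60000.0 / hr_bpm
        t_sat1, t_sat2 = seq.t_sats(rr)
        n_idle = compute_idle_beats(rr, seq.target_recovery_ms)
        recovery = n_idle * rr
        for t1 in t1_grid:
            sp = TissueSpecies(t1=t1)
            s1 = relax(saturate(sp.m0, seq.sat_efficiency), sp, t_sat1)
            s2 = relax(saturate(sp.m0, seq.sat_efficiency), sp, t_sat2)
            s3 = relax(0.0, sp, recovery)
            rows.append((t1, hr_bpm, t_sat1, t_sat2, recovery, s1, s2, s3))
    return pd.DataFrame(
        rows,
        columns=["t1_ms", "hr_bpm", "t_sat1_ms", "t_sat2_ms", "recovery_ms",
                 "s1", "s2", "s3"],
    )
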