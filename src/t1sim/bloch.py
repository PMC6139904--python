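"""Closed-form longitudinal-magnetization primitives.

Everything the sequence simulator does is composed from three operations on
the longitudinal magnetization Mz of a single tissue species:

* :func:`saturate` — a saturation pre-pulse of efficiency eta scales Mz by
  (1 - eta); a perfect pulse (eta = 1) nulls it exactly.
* :func:`relax` — free T1 recovery toward the equilibrium value M0,
  ``m0 + (mz - m0) * exp(-t / t1)``.
* :func:`spgr_train` — an ideally spoiled gradient-echo (SPGR) readout train:
  each low-flip pulse samples ``mz * sin(alpha)`` of transverse signal,
  projects the longitudinal component onto ``mz * cos(alpha)``, and relaxes
  for one TR before the next pulse.  Transverse magnetization is assumed
  perfectly spoiled every TR, so no transverse coherence history is carried.

T2 is carried on :class:`TissueSpecies` purely as phantom metadata: with an
ideally spoiled readout and TE folded into the (arbitrary) signal scale, the
longitudinal evolution modeled here never consults it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

__all__ = [
    "TissueSpecies",
    "RFReadoutParams",
    "saturate",
    "relax",
    "spgr_train",
]


@dataclass(frozen=True)
class TissueSpecies:
    """One voxel class or phantom vial: T1/T2 (ms) and equilibrium Mz."""

    t1: float
    t2: Optional[float] = None
    m0: float = 1.0

    def __post_init__(self) -> None:
        if not self.t1 > 0:
            raise ValueError(f"t1 must be > 0, got {self.t1}")
        if not self.m0 > 0:
            raise ValueError(f"m0 must be > 0, got {self.m0}")
        if self.t2 is not None and not self.t2 > 0:
            raise ValueError(f"t2 must be > 0 if given, got {self.t2}")


@dataclass(frozen=True)
class RFReadoutParams:
    """SPGR readout train parameters.

    ``n_readouts = 0`` selects an idealized readout: the sampled signal is the
    longitudinal magnetization itself and the (unmodeled) train is assumed to
    consume what remains of it, mirroring the approximation that Mz is
    negligible after a multi-pulse SPGR readout.
    """

    flip_angle_deg: float = 18.0
    tr_ms: float = 2.28
    n_readouts: int = 33
    profile_order: str = "centric"

    def __post_init__(self) -> None:
        if not 0 < self.flip_angle_deg < 90:
            raise ValueError(
                f"flip_angle_deg must be in (0, 90), got {self.flip_angle_deg}"
            )
        if not self.tr_ms > 0:
            raise ValueError(f"tr_ms must be > 0, got {self.tr_ms}")
        if self.n_readouts < 0:
            raise ValueError(f"n_readouts must be >= 0, got {self.n_readouts}")
        if self.profile_order not in ("centric", "linear"):
            raise ValueError(
                f"profile_order must be 'centric' or 'linear', got "
                f"{self.profile_order!r}"
            )

    @property
    def duration_ms(self) -> float:
        """Total train duration (n_readouts * TR)."""
        return self.n_readouts * self.tr_ms

    @property
    def kcenter_pulse(self) -> int:
        """1-based index of the pulse that samples the k-space center."""
        if self.n_readouts == 0:
            return 0
        if self.profile_order == "centric":
            return 1
        return math.ceil(self.n_readouts / 2)


def saturate(mz: float, efficiency: float) -> float:
    """Apply a saturation pulse of the given efficiency to Mz.

    Efficiency 1 nulls the magnetization exactly; efficiency 0 is a no-op.
    """
    if not 0.0 <= efficiency <= 1.0:
        raise ValueError(f"saturation efficiency must be in [0, 1], got {efficiency}")
    return mz * (1.0 - efficiency)


def relax(mz, species: TissueSpecies, t):
    """Free longitudinal recovery of ``mz`` toward ``species.m0`` over ``t`` ms.

    Accepts scalars or arrays for ``mz`` and ``t`` (broadcast together).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("relaxation duration t must be >= 0")
    mz = np.asarray(mz, dtype=float)
    out = species.m0 + (mz - species.m0) * np.exp(-t / species.t1)
    out = np.where(t == 0, mz, out)  # t = 0 returns mz exactly, no rounding
    if out.ndim == 0:
        return float(out)
    return out


def spgr_train(
    mz_in: float, species: TissueSpecies, rf: RFReadoutParams
) -> Tuple[float, float]:
    """Run one ideally spoiled SPGR readout train.

    Returns ``(signal_at_kcenter, mz_out)`` where the signal is the transverse
    component ``mz * sin(alpha)`` sampled at the k-space-center pulse
    (pulse 1 for centric ordering, the middle pulse for linear) and ``mz_out``
    is the longitudinal magnetization after the final pulse plus one TR of
    recovery.

    The per-pulse recursion ``mz <- (mz cos a) E1 + m0 (1 - E1)`` with
    ``E1 = exp(-TR/T1)`` is linear, so it is evaluated in closed form:
    with ``lam = E1 cos(a)``, the magnetization seen by pulse j (1-based) is
    ``lam**(j-1) * mz_in + m0 (1 - E1)(1 - lam**(j-1)) / (1 - lam)``.
    """
    if rf.n_readouts == 0:
        # Idealized sampling mode: report Mz directly; the unmodeled train is
        # assumed to consume the remaining longitudinal magnetization.
        return float(mz_in), 0.0

    alpha = math.radians(rf.flip_angle_deg)
    cos_a, sin_a = math.cos(alpha), math.sin(alpha)
    e1 = math.exp(-rf.tr_ms / species.t1)
    lam = e1 * cos_a

    def mz_before_pulse(j: int) -> float:
        w = lam ** (j - 1)
        return w * mz_in + species.m0 * (1.0 - e1) * (1.0 - w) / (1.0 - lam)

    signal = mz_before_pulse(rf.kcenter_pulse) * sin_a
    mz_out = mz_before_pulse(rf.n_readouts + 1)
    return float(signal), float(mz_out)
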