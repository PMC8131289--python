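"""Deterministic assay arithmetic for brain-penetration studies.

Implements the calculation chain that turns raw transwell, equilibrium-dialysis
and in vivo concentration measurements into the unbound brain-to-plasma
partition coefficient Kp,uu,brain:

* apparent permeability Papp = (dC_r/dt) * V_r / (A * C0)  [cm/s]
* efflux ratio ER = Papp(B->A) / Papp(A->B)
* fu,plasma = C_buffer / C_plasma
* fu,brain  = 1 / (D * (1/fu,brain' - 1) + 1)   (dilution correction of the
  fraction measured in diluted brain homogenate; D = 5 for 20% w/v)
* Kp,uu,brain = (fu,brain * C_brain) / (fu,plasma * C_plasma)
* a steady-state acceptance check: Kp,uu at two sampling times must agree
  within 2-fold (boundary inclusive).

All functions are pure; the table-level driver is :func:`derive_table`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# Transwell geometry of the MDCK monolayer assay.
APICAL_VOLUME_ML = 0.075
BASOLATERAL_VOLUME_ML = 0.25
MEMBRANE_AREA_CM2 = 0.0804
#: Default brain-homogenate dilution factor (20% w/v homogenate).
DEFAULT_DILUTION_FACTOR = 5.0


class Direction(enum.Enum):
    A_TO_B = "A_to_B"
    B_TO_A = "B_to_A"


class Matrix(enum.Enum):
    PLASMA = "plasma"
    BRAIN_HOMOGENATE = "brain_homogenate"


@dataclass(frozen=True)
class TransportAssay:
    """One transwell permeation measurement.

    ``times_s`` and ``receiver_concentrations_um`` are parallel arrays of
    sampling times (seconds) and cumulative receiver-chamber concentrations
    (µM).  ``v_r`` is the receiver volume in mL, ``a`` the monolayer area in
    cm², ``c0`` the initial donor concentration in µM.
    """

    times_s: tuple[float, ...]
    receiver_concentrations_um: tuple[float, ...]
    v_r: float
    a: float = MEMBRANE_AREA_CM2
    c0: float = 2.0
    direction: Direction = Direction.A_TO_B

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        c = np.asarray(self.receiver_concentrations_um, dtype=float)
        if t.size == 0:
            raise ValueError("at least one time point is required")
        if t.size != c.size:
            raise ValueError("times and concentrations must align")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(t <= 0) and t.size == 1:
            raise ValueError("a single time point must be positive")
        if np.all(t == 0):
            raise ValueError("all-zero times carry no flux information")
        if np.any(c < 0):
            raise ValueError("receiver concentrations must be nonnegative")
        for name in ("v_r", "a", "c0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class BindingMeasurement:
    """Paired buffer/matrix concentrations from equilibrium dialysis."""

    c_buffer: float
    c_matrix: float
    matrix: Matrix
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.c_buffer < 0 or self.c_matrix < 0:
            raise ValueError("concentrations must be nonnegative")
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")


@dataclass(frozen=True)
class BrainPenetrationRecord:
    fu_plasma: float
    fu_brain: float
    c_plasma: float
    c_brain: float


@dataclass
class FractionUnbound:
    """An unbound fraction plus an out-of-range flag.

    Dialysis occasionally yields buffer > matrix concentrations; the value is
    reported as measured and flagged rather than clipped, so downstream
    filtering stays explicit.
    """

    value: float
    out_of_range: bool = field(default=False)

    def __float__(self) -> float:  # pragma: no cover - convenience
        return self.value


def apparent_permeability(assay: TransportAssay) -> float:
    """Apparent permeability coefficient Papp in cm/s.

    The receiver accumulation slope dC_r/dt is an ordinary least-squares fit
    through the origin of concentration vs time; with a single time point this
    reduces to C_r(t)/t.
    """
    t = np.asarray(assay.times_s, dtype=float)
    c = np.asarray(assay.receiver_concentrations_um, dtype=float)
    # OLS slope through the origin: sum(t*c)/sum(t^2)
    slope = float(np.dot(t, c) / np.dot(t, t))
    return slope * assay.v_r / (assay.a * assay.c0)


def efflux_ratio(papp_b_to_a: float, papp_a_to_b: float) -> float:
    """ER = Papp(B->A) / Papp(A->B); values < 1 (net influx-like) are allowed."""
    if papp_a_to_b <= 0:
        raise ValueError("A->B permeability must be positive to form a ratio")
    if papp_b_to_a <= 0:
        raise ValueError("B->A permeability must be positive to form a ratio")
    return papp_b_to_a / papp_a_to_b


def fraction_unbound_plasma(m: BindingMeasurement) -> FractionUnbound:
    """fu,plasma = C_buffer / C_plasma, flagged (not clipped) when > 1."""
    if m.matrix is not Matrix.PLASMA:
        raise ValueError("measurement is not a plasma measurement")
    if m.c_matrix <= 0:
        raise ValueError("plasma concentration must be positive")
    fu = m.c_buffer / m.c_matrix
    return FractionUnbound(fu, out_of_range=fu > 1.0)


def fraction_unbound_brain(fu_prime: float, dilution_factor: float = DEFAULT_DILUTION_FACTOR) -> float:
    """Undiluted-brain unbound fraction from the diluted-homogenate value.

    fu,brain = 1 / (D * (1/fu' - 1) + 1).  At fu' = 1 the result is 1 for any
    dilution; at D = 1 the measured value is returned unchanged.
    """
    if not 0 < fu_prime <= 1:
        raise ValueError("fu_prime must lie in (0, 1]")
    if dilution_factor < 1:
        raise ValueError("dilution_factor must be >= 1")
    return 1.0 / (dilution_factor * (1.0 / fu_prime - 1.0) + 1.0)


def dilute_fraction_unbound(fu: float, dilution_factor: float) -> float:
    """Inverse of :func:`fraction_unbound_brain`: the fu' a D-fold diluted
    homogenate would show for a tissue with true unbound fraction ``fu``."""
    if not 0 < fu <= 1:
        raise ValueError("fu must lie in (0, 1]")
    if dilution_factor < 1:
        raise ValueError("dilution_factor must be >= 1")
    return 1.0 / ((1.0 / fu - 1.0) / dilution_factor + 1.0)


def kpuu_brain(r: BrainPenetrationRecord) -> float:
    """Kp,uu,brain = (fu,brain * C_brain) / (fu,plasma * C_plasma)."""
    for name in ("fu_plasma", "fu_brain", "c_plasma", "c_brain"):
        if getattr(r, name) <= 0:
            raise ValueError(f"{name} must be strictly positive for Kp,uu")
    return (r.fu_brain * r.c_brain) / (r.fu_plasma * r.c_plasma)


def steady_state_check(kpuu_early: float, kpuu_late: float) -> tuple[bool, float]:
    """2-fold agreement between sampling times, boundary inclusive.

    Returns ``(ok, fold_difference)`` where fold_difference >= 1.
    """
    if kpuu_early <= 0 or kpuu_late <= 0:
        raise ValueError("Kp,uu values must be positive")
    fold = max(kpuu_early / kpuu_late, kpuu_late / kpuu_early)
    return fold <= 2.0, fold


def derive_table(table: pd.DataFrame) -> pd.DataFrame:
    """Append derived columns to a canonical compound table.

    Requires columns er_mdr1, er_bcrp, fu_plasma, fu_brain_prime,
    dilution_factor, c_plasma_t1, c_brain_t1, c_plasma_t2, c_brain_t2.
    Adds fu_brain, kpuu_t1, kpuu_t2, kpuu (the later time point, used for
    modelling), steady_state_ok, fold_difference and fu_flag.
    """
    out = table.copy()
    fu_brain = np.array([
        fraction_unbound_brain(fp, d)
        for fp, d in zip(out["fu_brain_prime"], out["dilution_factor"])
    ])
    out["fu_brain"] = fu_brain
    out["fu_flag"] = (out["fu_plasma"] > 1) | (out["fu_brain_prime"] > 1)

    def _kpuu(cp: float, cb: float, fp: float, fb: float) -> float:
        return kpuu_brain(BrainPenetrationRecord(fu_plasma=fp, fu_brain=fb, c_plasma=cp, c_brain=cb))

    out["kpuu_t1"] = [
        _kpuu(cp, cb, fp, fb)
        for cp, cb, fp, fb in zip(out["c_plasma_t1"], out["c_brain_t1"], out["fu_plasma"], fu_brain)
    ]
    out["kpuu_t2"] = [
        _kpuu(cp, cb, fp, fb)
        for cp, cb, fp, fb in zip(out["c_plasma_t2"], out["c_brain_t2"], out["fu_plasma"], fu_brain)
    ]
    checks = [steady_state_check(a, b) for a, b in zip(out["kpuu_t1"], out["kpuu_t2"])]
    out["steady_state_ok"] = [ok for ok, _ in checks]
    out["fold_difference"] = [fd for _, fd in checks]
    # Modelling uses the later sampling time.
    out["kpuu"] = out["kpuu_t2"]
    return out
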