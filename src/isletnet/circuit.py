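"""Steady-state equivalent circuit of beta-to-delta-cell electrical coupling.

A driver beta-cell and a follower delta-cell joined by a gap junction of
conductance g form, at steady state, a voltage divider between the junction
and the follower's input resistance R: a voltage deflection dV_pre imposed on
the driver appears in the follower attenuated by the coupling coefficient

    k = dV_post / dV_pre = gR / (1 + gR).

Delta-cells have GOhm-scale input resistance, so even a tens-of-picosiemens
junction transmits a sizeable fraction of the beta-cell's K_ATP-driven
hyperpolarisation — and, equivalently, only picoampere currents are needed to
silence delta-cell electrical activity.

Unit convention, fixed project-wide: conductance in pS, resistance in GOhm,
voltage in mV, current in pA. The products pS*GOhm and pS*mV are dimensionless
and pA respectively after a factor of 1e-3, applied by the helpers below.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

#: pS * GOhm -> dimensionless; pS * mV -> pA.
_PS_TIMES_GOHM = 1e-3
_PS_TIMES_MV_TO_PA = 1e-3


@dataclass(frozen=True)
class CouplingCircuit:
    """Passive two-cell circuit: junctional conductance and follower input resistance."""

    g_gap_pS: float
    r_post_GOhm: float

    def __post_init__(self) -> None:
        if self.g_gap_pS < 0:
            raise ValueError("gap-junction conductance must be >= 0")
        if self.r_post_GOhm <= 0:
            raise ValueError("follower input resistance must be positive")


@dataclass(frozen=True)
class CouplingEstimate:
    """Coupling coefficient and conductance inferred from paired deflections.

    ``k_sem`` and ``g_gap_sem_pS`` are first-order (delta-method) propagated
    standard errors, present only when the deflection s.e.m. values were
    supplied to :func:`estimate_gap_conductance`.
    """

    k: float
    g_gap_pS: float
    dv_pre_mV: float
    dv_post_mV: float
    r_post_GOhm: float
    k_sem: float | None = None
    g_gap_sem_pS: float | None = None


@dataclass(frozen=True)
class PulseMeasurement:
    """Voltage step and steady-state current response of one cell."""

    dv_mV: float
    di_pA: float

    def __post_init__(self) -> None:
        if self.dv_mV == 0:
            raise ValueError("voltage step must be nonzero")


def coupling_coefficient(circuit: CouplingCircuit) -> float:
    """Steady-state coupling coefficient k = gR / (1 + gR), in [0, 1)."""
    gr = circuit.g_gap_pS * circuit.r_post_GOhm * _PS_TIMES_GOHM
    return gr / (1.0 + gr)


def estimate_gap_conductance(
    dv_pre_mV: float,
    dv_post_mV: float,
    r_post_GOhm: float,
    dv_pre_sem_mV: float | None = None,
    dv_post_sem_mV: float | None = None,
) -> CouplingEstimate:
    """Invert the voltage divider: conductance from paired voltage deflections.

    Given the driver deflection dV_pre, the follower deflection dV_post and
    the follower input resistance R, computes k = dV_post/dV_pre and
    g = k / ((1 - k) R), reported in pS. Requires |dV_post| < |dV_pre| (k >= 1
    is unphysical for passive coupling) and matching signs (or dV_post = 0).

    When both deflection s.e.m. values are given, standard errors of k and g
    are propagated to first order assuming independent measurement errors:
    (s_k/k)^2 = (s_pre/dV_pre)^2 + (s_post/dV_post)^2 and
    s_g = s_k / ((1-k)^2 R).
    """
    if dv_pre_mV == 0:
        raise ValueError("driver deflection must be nonzero")
    if abs(dv_post_mV) >= abs(dv_pre_mV):
        raise ValueError(
            "follower deflection must be smaller in magnitude than the "
            "driver deflection (k >= 1 is unphysical for passive coupling)"
        )
    if dv_post_mV != 0 and (dv_post_mV > 0) != (dv_pre_mV > 0):
        raise ValueError("deflections must have the same sign")
    if r_post_GOhm <= 0:
        raise ValueError("follower input resistance must be positive")
    k = dv_post_mV / dv_pre_mV
    g = k / ((1.0 - k) * r_post_GOhm) / _PS_TIMES_GOHM
    k_sem = g_sem = None
    if dv_pre_sem_mV is not None and dv_post_sem_mV is not None:
        if dv_pre_sem_mV < 0 or dv_post_sem_mV < 0:
            raise ValueError("s.e.m. values must be >= 0")
        if dv_post_mV == 0:
            k_sem = abs(dv_post_sem_mV / dv_pre_mV)
        else:
            k_sem = abs(k) * math.hypot(
                dv_pre_sem_mV / dv_pre_mV, dv_post_sem_mV / dv_post_mV
            )
        g_sem = k_sem / ((1.0 - k) ** 2 * r_post_GOhm) / _PS_TIMES_GOHM
    return CouplingEstimate(
        k=k,
        g_gap_pS=g,
        dv_pre_mV=dv_pre_mV,
        dv_post_mV=dv_post_mV,
        r_post_GOhm=r_post_GOhm,
        k_sem=k_sem,
        g_gap_sem_pS=g_sem,
    )


def junctional_current(g_gap_pS: float, dv_pre_mV: float) -> float:
    """Current through the junction (pA) for a driver deflection held by clamp."""
    if g_gap_pS < 0:
        raise ValueError("gap-junction conductance must be >= 0")
    return g_gap_pS * dv_pre_mV * _PS_TIMES_MV_TO_PA


def membrane_resistance(pulse: PulseMeasurement) -> float:
    """Input resistance by Ohm's law, R = dV/dI, in GOhm.

    A zero current response means no measurable conductance; the IEEE
    infinity is returned as the infinite-resistance flag.
    """
    if pulse.di_pA == 0:
        return math.inf
    return pulse.dv_mV / pulse.di_pA


def min_suppressive_current(
    delta_v_required_mV: float, r_m_GOhm: float
) -> float:
    """Smallest hyperpolarising current (pA, negative) producing the required deflection.

    Steady-state Ohmic estimate |I| = dV / R; the sign is negative by the
    convention that suppressive (hyperpolarising) injections are inward.
    """
    if delta_v_required_mV <= 0:
        raise ValueError("required hyperpolarisation must be positive")
    if r_m_GOhm <= 0:
        raise ValueError("membrane resistance must be positive")
    return -delta_v_required_mV / r_m_GOhm
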