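"""Conversion of process conditions into pump and bath operating parameters.

The rig merges three streams: a concentrated lanolin feedstock solution
(pump 1), an alkali solution (pump 2) and a diluent (pump 3). The diluent
brings the lanolin solution from its stock mass fraction ``w0`` down to the
target ``wi``; the alkali stream delivers ``lam_a`` kg of alkali per kg of
lanolin. Requiring (i) the merged stream to fill the reactor coil in
exactly the reaction time ``t0``, (ii) the diluted lanolin fraction to be
``wi`` and (iii) the alkali ratio to be ``lam_a`` fixes all three
volumetric flow rates in closed form (volume additivity assumed on
merging):

    Q1 = (Vr / t0) / (1 + rho1*w0*lam_a/(wj*rho2) + (rho1*w0/wi - rho1)/rho3)
    Q2 = rho1*w0*Q1*lam_a / (wj*rho2)
    Q3 = (rho1*w0*Q1/wi - rho1*Q1) / rho3

The residence time seen by material is t1 = t0 + t2 + t3 with t2 = V1/Q1
the pump-to-junction transfer time and t3 the equilibration time.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import HardwareConfig, MaterialProperties, ProcessConditions

__all__ = ["OperatingParameters", "MassBalanceReport", "compute_operating_parameters", "check_mass_balance"]


@dataclass
class OperatingParameters:
    """Pump flow rates (mL/min), residence-time breakdown (min) and bath setpoint (degC)."""

    Q1: float
    Q2: float
    Q3: float
    t1: float
    t2: float
    bath_setpoint: float


@dataclass
class MassBalanceReport:
    """Residuals of the three algebraic identities behind the flow equations.

    All three are ~0 for parameters produced by
    :func:`compute_operating_parameters`:
    ``lanolin_fraction`` — merged-stream lanolin mass fraction minus wi;
    ``alkali_ratio`` — delivered alkali-to-lanolin mass ratio minus lam_a;
    ``total_flow`` — (Q1+Q2+Q3) minus Vr/t0.
    """

    lanolin_fraction: float
    alkali_ratio: float
    total_flow: float

    @property
    def max_abs(self) -> float:
        return max(abs(self.lanolin_fraction), abs(self.alkali_ratio), abs(self.total_flow))


def compute_operating_parameters(
    pc: ProcessConditions, mp: MaterialProperties, hw: HardwareConfig
) -> OperatingParameters:
    """Convert process conditions to pump flow rates and residence times."""
    if mp.w0 < pc.wi:
        raise ValueError(
            f"infeasible dilution: feedstock mass fraction w0={mp.w0} is below the "
            f"target lanolin solution mass fraction wi={pc.wi}"
        )
    denom = 1.0 + (mp.rho1 * mp.w0 * pc.lam_a) / (mp.wj * mp.rho2) + (mp.rho1 * mp.w0 / pc.wi - mp.rho1) / mp.rho3
    q1 = (hw.Vr / pc.t0) / denom
    q2 = (mp.rho1 * mp.w0 * q1 * pc.lam_a) / (mp.wj * mp.rho2)
    q3 = (mp.rho1 * mp.w0 * q1 / pc.wi - mp.rho1 * q1) / mp.rho3
    t2 = hw.V1 / q1
    t1 = pc.t0 + t2 + hw.t3
    return OperatingParameters(Q1=q1, Q2=q2, Q3=q3, t1=t1, t2=t2, bath_setpoint=pc.T)


def check_mass_balance(
    op: OperatingParameters, pc: ProcessConditions, mp: MaterialProperties, hw: HardwareConfig
) -> MassBalanceReport:
    """Diagnostic residuals verifying the flow-rate algebra for given parameters."""
    merged_fraction = (op.Q1 * mp.rho1 * mp.w0) / (op.Q1 * mp.rho1 + op.Q3 * mp.rho3)
    alkali_ratio = (op.Q2 * mp.rho2 * mp.wj) / (op.Q1 * mp.rho1 * mp.w0)
    return MassBalanceReport(
        lanolin_fraction=merged_fraction - pc.wi,
        alkali_ratio=alkali_ratio - pc.lam_a,
        total_flow=(op.Q1 + op.Q2 + op.Q3) - hw.Vr / pc.t0,
    )
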