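"""In vitro–in vivo extrapolation to steady-state dosimetry.

Converts the two measured toxicokinetic parameters — fraction unbound in
plasma (f_up) and hepatocyte intrinsic clearance (Cl_int) — into a human
steady-state plasma concentration under continuous daily dosing, and into
the administered equivalent dose (AED) matching an in vitro bioactivity
concentration:

* fraction unbound in blood   f_ub = min(1, f_up / Rb)
* renal clearance             Cl_renal = GFR × f_ub
* scaled intrinsic clearance  CL_u = Cl_int × hepatocellularity × liver mass
* hepatic clearance           Cl_hep = Qh·f_ub·CL_u / (Qh + f_ub·CL_u)
  (well-stirred liver model, bounded above by liver blood flow Qh)
* steady state                C_ss = molar dose rate / (Cl_renal + Cl_hep)
* dose conversion             AED = LOEC / C_ss × dose

C_ss assumes the daily dose is delivered as a continuous equivalent
infusion. Default physiological scalars describe a 70 kg human: GFR
6.7 L/h, liver blood flow 90 L/h, 110×10⁶ hepatocytes per g liver and a
1596 g liver; the default blood:plasma ratio of 0.55 applies to ionized
chemicals, while neutral chemicals require a chemical-specific Rb.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "IVIVEParams",
    "IVIVEResult",
    "fraction_unbound_blood",
    "renal_clearance",
    "scaled_intrinsic_clearance",
    "hepatic_clearance_whole_liver",
    "steady_state_css",
    "administered_equivalent_dose",
    "run_ivive",
]


@dataclass
class IVIVEParams:
    """Physiological scalars for the IVIVE calculation (all must be positive)."""

    body_weight: float = 70.0        # kg
    gfr: float = 6.7                 # L/h, glomerular filtration rate
    rb_default: float = 0.55         # blood:plasma ratio for ionized chemicals
    liver_blood_flow: float = 90.0   # L/h (Qh)
    hepatocellularity: float = 110.0  # 10^6 cells per g liver
    liver_mass: float = 1596.0       # g
    dose: float = 1.0                # mg/kg/day

    def __post_init__(self) -> None:
        for name in (
            "body_weight",
            "gfr",
            "rb_default",
            "liver_blood_flow",
            "hepatocellularity",
            "liver_mass",
            "dose",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"IVIVEParams.{name} must be > 0")


@dataclass
class IVIVEResult:
    """Per-chemical IVIVE outputs at the configured dose."""

    chem_id: str
    fub: float            # fraction unbound in blood, capped at 1
    cl_renal: float       # L/h
    cl_hep: float         # L/h
    css: float            # µM
    aed: float = np.nan   # mg/kg/day; NaN when no LOEC is available


def fraction_unbound_blood(fup: float, rb: float) -> float:
    """Fraction unbound in blood: ``min(1, fup / rb)``."""
    if not 0 < fup <= 1:
        raise ValueError(f"fup must lie in (0, 1], got {fup}")
    if not rb > 0:
        raise ValueError(f"rb must be > 0, got {rb}")
    return min(1.0, fup / rb)


def renal_clearance(fub: float, gfr: float = 6.7) -> float:
    """Nonmetabolic renal clearance (L/h): glomerular filtration of unbound drug."""
    if not 0 < fub <= 1:
        raise ValueError(f"fub must lie in (0, 1], got {fub}")
    return gfr * fub


def scaled_intrinsic_clearance(clint: float, params: IVIVEParams) -> float:
    """Scale Cl_int (µL/(min × 10⁶ cells)) to whole-liver clearance (L/h)."""
    if clint < 0:
        raise ValueError(f"clint must be >= 0, got {clint}")
    # µL/min/10^6 cells × 10^6 cells/g × g = µL/min; × 60 min/h × 1e-6 L/µL
    return clint * params.hepatocellularity * params.liver_mass * 60.0 * 1e-6


def hepatic_clearance_whole_liver(
    clint: float, fub: float, params: Optional[IVIVEParams] = None
) -> float:
    """Whole-liver hepatic clearance (L/h) via the well-stirred model.

    ``Cl_hep = Qh · fub · CL_u / (Qh + fub · CL_u)``, which is strictly
    below the liver blood flow Qh and exactly 0 when ``clint`` is 0.
    """
    params = params or IVIVEParams()
    clu = scaled_intrinsic_clearance(clint, params)
    if clu == 0.0:
        return 0.0
    qh = params.liver_blood_flow
    return qh * fub * clu / (qh + fub * clu)


def molar_dose_rate(mol_weight: float, params: Optional[IVIVEParams] = None) -> float:
    """Continuous-infusion equivalent of the daily dose, in µmol/h."""
    params = params or IVIVEParams()
    if not mol_weight > 0:
        raise ValueError("mol_weight must be > 0")
    # mg/kg/day × kg = mg/day; / (g/mol) = mmol/day; ×1000 → µmol/day; /24 → µmol/h
    return params.dose * params.body_weight / mol_weight * 1000.0 / 24.0


def steady_state_css(
    mol_weight: float,
    cl_renal: float,
    cl_hep: float,
    params: Optional[IVIVEParams] = None,
) -> float:
    """Steady-state plasma concentration (µM) at the configured dose.

    ``C_ss = molar dose rate / (Cl_renal + Cl_hep)`` with clearances in L/h,
    so µmol/h ÷ L/h = µmol/L = µM. Zero total clearance yields ``inf``
    (flagged, not raised): no elimination route means no steady state.
    """
    params = params or IVIVEParams()
    total = cl_renal + cl_hep
    rate = molar_dose_rate(mol_weight, params)
    if total <= 0:
        return float("inf")
    return rate / total


def administered_equivalent_dose(loec: float, css: float, dose: float = 1.0) -> float:
    """External dose (mg/kg/day) whose C_ss equals the bioactive concentration.

    ``AED = LOEC / C_ss × dose`` where ``css`` was computed at ``dose``.
    """
    if not loec > 0:
        raise ValueError("loec must be > 0")
    if not css > 0:
        raise ValueError("css must be > 0")
    return loec / css * dose


def run_ivive(
    chem_id: str,
    fup: float,
    clint: float,
    mol_weight: float,
    loec: Optional[float] = None,
    rb: Optional[float] = None,
    ionization_class: str = "ionized",
    params: Optional[IVIVEParams] = None,
) -> IVIVEResult:
    """Full IVIVE chain for one chemical.

    ``rb`` falls back to ``params.rb_default`` for ionized chemicals;
    neutral chemicals must supply a chemical-specific blood:plasma ratio
    (partitioning is not predicted here).
    """
    params = params or IVIVEParams()
    if rb is None or not np.isfinite(rb):
        if ionization_class == "neutral":
            raise ValueError(
                f"{chem_id}: neutral chemicals require a chemical-specific rb"
            )
        rb = params.rb_default
    fub = fraction_unbound_blood(fup, rb)
    cl_r = renal_clearance(fub, params.gfr)
    cl_h = hepatic_clearance_whole_liver(clint, fub, params)
    css = steady_state_css(mol_weight, cl_r, cl_h, params)
    aed = np.nan
    if loec is not None and np.isfinite(loec) and np.isfinite(css) and css > 0:
        aed = administered_equivalent_dose(loec, css, params.dose)
    return IVIVEResult(chem_id=chem_id, fub=fub, cl_renal=cl_r, cl_hep=cl_h, css=css, aed=aed)
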