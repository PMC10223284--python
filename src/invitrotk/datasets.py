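"""Bundled example dataset: measured TK inputs for 13 data-poor PFAS.

These are published in vitro measurements (fraction unbound in plasma and
hepatocyte intrinsic clearance) together with the IVIVE outputs reported
alongside them, for thirteen volatile PFAS spanning amides, diols, glycols,
a fluorotelomer alcohol and a tosylate. They serve as a worked example for
:mod:`invitrotk.ivive` and as a regression oracle: recomputing the chain
from ``fup``/``clint`` with the default physiological scalars reproduces
the reported clearances within 1% and C_ss/AED within 2% (at the printed
precision).

The single neutral chemical (the tosylate) carries its chemical-specific
blood:plasma ratio; all ionized chemicals use the 0.55 default.
"""

from __future__ import annotations

import io

import pandas as pd

__all__ = ["load_ivive_examples"]

# columns: identifier, name, MW (g/mol), measured f_up, measured Cl_int
# (µL/min/10^6 cells), bioactivity LOEC (µM), ionization class,
# blood:plasma ratio, then the reported IVIVE outputs (Cl_renal L/h,
# Cl_hep L/h, C_ss µM, AED mg/kg/day).
_CSV = """\
chem_id,name,mol_weight,fup,clint,loec,ionization_class,rb,pub_cl_renal,pub_cl_hep,pub_css,pub_aed
DTXSID3059927,Hexafluoroamylene glycol,212.09,0.6770,0.00,2,ionized,,6.7,0.000,2.07,0.966
DTXSID0059871,Pentafluoropropionamide,163.05,0.8089,0.00,20,ionized,,6.7,0.000,2.69,7.431
DTXSID80310730,Octafluoroadipamide,288.10,0.8201,2.95,2,ionized,,6.7,23.099,0.34,5.840
DTXSID10382147,"3-(Perfluoro-2-butyl) propane-1,2-diol",294.12,0.3696,5.88,2,ionized,,4.5024,28.460,0.30,6.595
DTXSID70381090,"1H,1H,8H,8H-Perfluoro-3,6-dioxaoctane-1,8-diol",294.10,0.2069,6.72,7,ionized,,2.5204,20.549,0.43,16.154
DTXSID70366226,Perfluoropentanamide,245.07,0.5417,14.68,7,ionized,,6.5989,56.570,0.19,36.860
DTXSID00380798,"1H,1H,11H,11H-Perfluorotetraethylene glycol",410.11,0.0128,19.93,2,ionized,,0.1559,4.634,1.50,1.336
DTXSID2060965,Heptafluorobutyramide,213.06,0.6030,19.95,20,ionized,,6.7,63.013,0.20,101.039
DTXSID30396867,"1H,1H,8H,8H-Perfluorooctane-1,8-diol",362.12,0.0560,20.01,7,ionized,,0.6822,17.326,0.45,15.526
DTXSID30340244,"1H,1H,7H-Perfluoroheptyl 4-methylbenzenesulfonate",486.27,0.0290,23.85,7,neutral,12.2975,0.0158,0.588,10.01,0.700
DTXSID60400587,Nonafluoropentanamide,263.03,0.1985,26.03,7,ionized,,2.4181,47.130,0.23,31.034
DTXSID1062122,4:2 Fluorotelomer alcohol,264.09,0.1680,37.71,2,ionized,,2.0465,51.672,0.21,9.651
DTXSID50369896,"1H,1H,10H,10H-Perfluorodecane-1,10-diol",462.13,0.0047,49.86,2,ionized,,0.0573,4.275,1.47,1.362
"""


def load_ivive_examples() -> pd.DataFrame:
    """Return the worked-example table (13 chemicals, inputs + reported outputs)."""
    return pd.read_csv(io.StringIO(_CSV), dtype={"chem_id": str})
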