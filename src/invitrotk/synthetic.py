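"""Synthetic raw-measurement generator with known ground truth.

Emulates the laboratory designs end to end so the whole pipeline is
testable without any instrument data:

* 15-point calibration curves, geometrically spaced over 1.75–1250 nM for
  the plasma matrix and 7–5000 nM for the hepatocyte matrix, with a
  7-injection low-level replicate set for eMDL/eLOQ estimation and blanks;
* the ultracentrifugation assay at a 10 µM assay concentration (250 nM at
  instrument after the plasma work-up dilution), three replicate
  experiments each contributing T1hr, T5hr and aqueous-fraction samples;
* the substrate-depletion assay at 1 µM (50 nM at instrument) and 50,000
  cells/100 µL, triplicate wells on a 0–240 min grid with cell-free and
  metabolically inactivated negative controls.

The measurement model matches the Bayesian likelihood by construction:
response ratio ~ Normal(b0 + b1·C + b2·C², sqrt(sigma0² + (cv·mu)²)), with
lognormal pipetting noise on the latent assay concentrations. A
``lognormal_errors`` switch swaps in multiplicative lognormal response
noise to test robustness to likelihood misspecification. Responses below
the batch's detection threshold (the eMDL implied by the truth curve) are
flagged below-detection.

All randomness flows from a single integer seed; identical spec + seed
yields byte-identical tables.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .calibration import emdl_t_multiplier
from .datamodel import MEASUREMENT_COLUMNS, validate_chemicals, validate_measurements

__all__ = [
    "CalibrationTruth",
    "NoiseSpec",
    "CalibrationDesign",
    "UCDesign",
    "DepletionDesign",
    "ChemicalTruth",
    "GeneratorSpec",
    "generate_calibration",
    "generate_uc_assay",
    "generate_depletion",
    "generate_chemical_bundle",
    "generate_cohort",
]


@dataclass
class CalibrationTruth:
    """True response curve: ratio = beta0 + beta1·C + beta2·C² (C in nM)."""

    beta0: float = 0.0
    beta1: float = 0.002
    beta2: float = 0.0

    def response(self, conc):
        c = np.asarray(conc, dtype=float)
        return self.beta0 + self.beta1 * c + self.beta2 * c**2


@dataclass
class NoiseSpec:
    """Measurement and pipetting noise.

    ``cv`` is the proportional response coefficient of variation (the ν of
    the heteroscedastic model), ``sigma0`` the constant response-scale
    floor, and ``pipette_sdlog`` the log-sd of the latent assay
    concentrations around nominal.
    """

    sigma0: float = 0.0005
    cv: float = 0.10
    pipette_sdlog: float = 0.05
    lognormal_errors: bool = False

    def __post_init__(self) -> None:
        if self.sigma0 < 0 or self.cv < 0 or self.pipette_sdlog < 0:
            raise ValueError("noise magnitudes must be >= 0")

    def perturb(self, mu: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        mu = np.asarray(mu, dtype=float)
        if self.lognormal_errors:
            out = mu * np.exp(rng.normal(0.0, self.cv, mu.shape))
            out = out + rng.normal(0.0, self.sigma0, mu.shape)
        else:
            sigma = np.sqrt(self.sigma0**2 + (self.cv * mu) ** 2)
            out = mu + rng.normal(0.0, 1.0, mu.shape) * sigma
        return out


@dataclass
class CalibrationDesign:
    """Calibration layout; defaults give the 15-point plasma-matrix curve."""

    n_levels: int = 15
    conc_min: float = 1.75
    conc_max: float = 1250.0
    n_replicates: int = 1
    n_mdl_replicates: int = 7   # injections of the low-end levels
    n_loq_levels: int = 4       # how many low levels carry the 7-injection set
    n_blanks: int = 2

    def levels(self) -> np.ndarray:
        return np.geomspace(self.conc_min, self.conc_max, self.n_levels)


#: hepatocyte-matrix calibration range
HEPATOCYTE_CALIBRATION = CalibrationDesign(conc_min=7.0, conc_max=5000.0)


@dataclass
class UCDesign:
    """Ultracentrifugation assay layout."""

    n_replicates: int = 3
    nominal_assay_uM: float = 10.0
    #: 1 volume sample + 3 volumes acetonitrile, then 1:10 in solvent
    dilution_factor: float = 40.0

    @property
    def nominal_instrument_nM(self) -> float:
        return self.nominal_assay_uM * 1000.0 / self.dilution_factor


@dataclass
class DepletionDesign:
    """Substrate-depletion assay layout."""

    timepoints: Sequence[float] = (0.0, 15.0, 30.0, 60.0, 120.0, 240.0)
    n_replicates: int = 3
    nominal_assay_uM: float = 1.0
    #: equal-volume acetonitrile crash, then 1 part sample + 9 parts solvent
    dilution_factor: float = 20.0
    cells_per_well: int = 50_000
    well_volume_ul: float = 100.0
    include_inactivated: bool = True

    @property
    def nominal_instrument_nM(self) -> float:
        return self.nominal_assay_uM * 1000.0 / self.dilution_factor


@dataclass
class ChemicalTruth:
    """Ground-truth parameters for one synthetic chemical."""

    chem_id: str
    true_fup: float = 0.1
    true_degradation: float = 1.0   # D: T5hr/T1hr concentration fraction
    true_k_met: float = 0.0         # 1/min
    true_k_bg: float = 0.0          # 1/min
    mol_weight: float = 300.0
    loec: Optional[float] = None
    ionization_class: str = "ionized"
    rb: Optional[float] = None
    name: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_fup <= 1.0:
            raise ValueError("true_fup must lie in [0, 1]")
        if not 0.0 < self.true_degradation <= 1.0:
            raise ValueError("true_degradation must lie in (0, 1]")
        if self.true_k_met < 0 or self.true_k_bg < 0:
            raise ValueError("rate constants must be >= 0")
        if not self.name:
            self.name = self.chem_id


@dataclass
class GeneratorSpec:
    """Everything needed to generate one synthetic study."""

    chemicals: list = field(default_factory=list)
    calibration_truth: CalibrationTruth = field(default_factory=CalibrationTruth)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    plasma_calibration: CalibrationDesign = field(default_factory=CalibrationDesign)
    hepatocyte_calibration: CalibrationDesign = field(
        default_factory=lambda: replace(HEPATOCYTE_CALIBRATION)
    )
    uc_design: UCDesign = field(default_factory=UCDesign)
    depletion_design: DepletionDesign = field(default_factory=DepletionDesign)
    censor: bool = True
    seed: int = 0

    def censor_limit_nM(self) -> float:
        """Detection threshold implied by the truth curve.

        The concentration-scale eMDL of the noise model at the blank:
        ``sd(back-calculated blank) × t(0.99, 6 df) = sigma0/beta1 × 3.14``.
        Zero when the generator is noiseless, so noiseless data are never
        censored.
        """
        if self.noise.sigma0 == 0.0:
            return 0.0
        return self.noise.sigma0 / self.calibration_truth.beta1 * emdl_t_multiplier()


def _rng_for(spec: GeneratorSpec, chem_id: str, purpose: str) -> np.random.Generator:
    """Deterministic, order-independent stream per (seed, chemical, purpose)."""
    return np.random.default_rng(
        [spec.seed, zlib.crc32(chem_id.encode()), zlib.crc32(purpose.encode())]
    )


def _rows(chem_id, assay, sample_type, batch_id, replicate, time_min, nominal, resp):
    n = len(resp)
    df = pd.DataFrame(
        {
            "chem_id": chem_id,
            "assay": assay,
            "sample_type": sample_type,
            "batch_id": batch_id,
            "replicate": replicate,
            "time_min": time_min,
            "nominal_conc": nominal,
            "response_ratio": np.asarray(resp, dtype=float),
            "below_detection": False,
        },
        columns=MEASUREMENT_COLUMNS,
        index=range(n),
    )
    return df.astype(
        {"replicate": int, "time_min": float, "nominal_conc": float,
         "response_ratio": float, "below_detection": bool}
    )


def _apply_censoring(spec: GeneratorSpec, df: pd.DataFrame) -> pd.DataFrame:
    thr = spec.calibration_truth.response(spec.censor_limit_nM())
    if not spec.censor or spec.censor_limit_nM() <= 0:
        df["response_ratio"] = df["response_ratio"].clip(lower=0.0)
        return df
    below = df["response_ratio"] < thr
    df.loc[below, "below_detection"] = True
    df.loc[below, "response_ratio"] = np.nan
    df["response_ratio"] = df["response_ratio"].clip(lower=0.0)
    return df


def generate_calibration(
    spec: GeneratorSpec,
    chem_id: str,
    batch_id: str,
    design: Optional[CalibrationDesign] = None,
) -> pd.DataFrame:
    """Generate calibration standards (plus blanks) for one (chemical, batch).

    The lowest ``n_loq_levels`` levels carry ``n_mdl_replicates`` injections
    each (the eMDL/eLOQ replicate sets); remaining levels carry
    ``n_replicates``.
    """
    design = design or spec.plasma_calibration
    if design.n_levels < 2:
        raise ValueError("calibration needs at least 2 levels")
    rng = _rng_for(spec, chem_id, f"cal:{batch_id}")
    levels = design.levels()
    frames = []
    for i, level in enumerate(levels):
        n = design.n_mdl_replicates if i < design.n_loq_levels else design.n_replicates
        mu = np.full(n, spec.calibration_truth.response(level))
        resp = spec.noise.perturb(mu, rng)
        frames.append(
            _rows(chem_id, "calibration", "standard", batch_id, np.arange(1, n + 1),
                  np.nan, level, resp)
        )
    blanks = spec.noise.perturb(np.zeros(design.n_blanks), rng)
    frames.append(
        _rows(chem_id, "calibration", "blank", batch_id,
              np.arange(1, design.n_blanks + 1), np.nan, np.nan, blanks)
    )
    df = pd.concat(frames, ignore_index=True)
    return _apply_censoring(spec, df)


def generate_uc_assay(
    spec: GeneratorSpec, chem: ChemicalTruth, batch_id: str
) -> pd.DataFrame:
    """Generate T1hr/T5hr/AF responses for one chemical.

    Latent concentrations: ``C_T1 ~ nominal × LogNormal(0, pipette_sdlog)``
    per replicate experiment, ``C_T5 = D·C_T1`` and ``C_AF = fup·C_T5``.
    """
    rng = _rng_for(spec, chem.chem_id, f"uc:{batch_id}")
    design = spec.uc_design
    nom = design.nominal_instrument_nM
    frames = []
    for rep in range(1, design.n_replicates + 1):
        c_t1 = nom * np.exp(rng.normal(0.0, spec.noise.pipette_sdlog))
        c_t5 = chem.true_degradation * c_t1
        c_af = chem.true_fup * c_t5
        for stype, conc in (("T1hr", c_t1), ("T5hr", c_t5), ("AF", c_af)):
            mu = spec.calibration_truth.response(conc)
            resp = spec.noise.perturb(np.array([mu]), rng)
            frames.append(
                _rows(chem.chem_id, "uc_ppb", stype, batch_id, rep, np.nan, np.nan, resp)
            )
    df = pd.concat(frames, ignore_index=True)
    return _apply_censoring(spec, df)


def generate_depletion(
    spec: GeneratorSpec, chem: ChemicalTruth, batch_id: str
) -> pd.DataFrame:
    """Generate whole-cell, cell-free and inactivated depletion series.

    The whole-cell series decays at ``k_met + k_bg``; both negative
    controls decay at ``k_bg`` alone. Each (condition, replicate) well has
    its own lognormal pipetting error on the initial concentration.
    """
    rng = _rng_for(spec, chem.chem_id, f"dep:{batch_id}")
    design = spec.depletion_design
    nom = design.nominal_instrument_nM
    conditions = [("hep_cells", chem.true_k_met + chem.true_k_bg),
                  ("cellfree_ctrl", chem.true_k_bg)]
    if design.include_inactivated:
        conditions.append(("inactivated_ctrl", chem.true_k_bg))
    times = np.asarray(design.timepoints, dtype=float)
    frames = []
    for stype, k in conditions:
        for rep in range(1, design.n_replicates + 1):
            c0 = nom * np.exp(rng.normal(0.0, spec.noise.pipette_sdlog))
            conc = c0 * np.exp(-k * times)
            mu = spec.calibration_truth.response(conc)
            resp = spec.noise.perturb(mu, rng)
            frames.append(
                _rows(chem.chem_id, "hep_clearance", stype, batch_id, rep, times,
                      np.nan, resp)
            )
    df = pd.concat(frames, ignore_index=True)
    return _apply_censoring(spec, df)


def generate_chemical_bundle(spec: GeneratorSpec, chem: ChemicalTruth) -> pd.DataFrame:
    """All measurement tables for one chemical: both assays plus their
    matrix-specific calibration batches."""
    parts = [
        generate_calibration(spec, chem.chem_id, "uc-day1", spec.plasma_calibration),
        generate_uc_assay(spec, chem, "uc-day1"),
        generate_calibration(spec, chem.chem_id, "hep-day1", spec.hepatocyte_calibration),
        generate_depletion(spec, chem, "hep-day1"),
    ]
    df = pd.concat(parts, ignore_index=True)
    return validate_measurements(df)


def generate_cohort(
    n_chemicals: int,
    seed: int = 0,
    spec: Optional[GeneratorSpec] = None,
    fup_median: float = 0.094,
    fup_sdlog: float = 1.3,
    p_no_clearance: float = 0.15,
    k_met_median: float = 0.008,
    k_met_sdlog: float = 0.8,
    k_bg_median: float = 0.002,
    k_bg_sdlog: float = 0.7,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Sample a synthetic chemical cohort and generate all its raw data.

    True f_up follows a right-skewed lognormal capped at 1 (matching the
    highly-bound, skewed binding distribution of volatile PFAS cohorts);
    Cl_int follows a mixture of a point mass at zero and a lognormal body.

    Returns ``(chemicals, truth, measurements)`` tables; ``truth`` carries
    the generating parameters for recovery scoring.
    """
    if n_chemicals < 1:
        raise ValueError("n_chemicals must be >= 1")
    spec = spec or GeneratorSpec()
    spec = replace(spec, seed=seed)
    rng = np.random.default_rng([seed, 0xC0F0])
    chems = []
    for i in range(n_chemicals):
        fup = float(min(1.0, np.exp(rng.normal(np.log(fup_median), fup_sdlog))))
        k_met = 0.0 if rng.random() < p_no_clearance else float(
            np.exp(rng.normal(np.log(k_met_median), k_met_sdlog))
        )
        k_bg = float(np.exp(rng.normal(np.log(k_bg_median), k_bg_sdlog)))
        chems.append(
            ChemicalTruth(
                chem_id=f"SYN{i:04d}",
                true_fup=max(fup, 1e-4),
                true_k_met=k_met,
                true_k_bg=k_bg,
                mol_weight=float(rng.uniform(150.0, 500.0)),
                loec=float(rng.choice([2.0, 7.0, 20.0])),
            )
        )
    spec = replace(spec, chemicals=chems)
    truth = pd.DataFrame(
        {
            "chem_id": [c.chem_id for c in chems],
            "true_fup": [c.true_fup for c in chems],
            "true_degradation": [c.true_degradation for c in chems],
            "true_k_met": [c.true_k_met for c in chems],
            "true_k_bg": [c.true_k_bg for c in chems],
            "true_clint": [2000.0 * c.true_k_met for c in chems],
        }
    )
    chemicals = validate_chemicals(
        pd.DataFrame(
            {
                "chem_id": [c.chem_id for c in chems],
                "name": [c.name for c in chems],
                "mol_weight": [c.mol_weight for c in chems],
                "category": "synthetic",
                "ionization_class": [c.ionization_class for c in chems],
                "loec": [c.loec for c in chems],
                "rb": [c.rb for c in chems],
            }
        )
    )
    measurements = pd.concat(
        [generate_chemical_bundle(spec, c) for c in chems], ignore_index=True
    )
    return chemicals, truth, measurements
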