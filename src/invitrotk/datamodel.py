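"""Domain types and table validation shared by every pipeline stage.

The package works on two tidy tables:

``measurements``
    One row per mass-spectrometry observation: an analyte:internal-standard
    response ratio together with its assay context (chemical, assay,
    sample type, batch/day, replicate, timepoint, nominal concentration).

``chemicals``
    One row per chemical: identifier, name, molecular weight, functional
    category, ionization class, and optional bioactivity LOEC and
    blood:plasma ratio.

Concentrations are carried *at instrument* (nM in the injected solution).
Dilution factors applied during sample work-up (acetonitrile crash and
solvent dilution) are recorded as metadata only: fraction unbound and
depletion slopes are ratios of concentrations diluted identically, so
applying the factors would only introduce a silent unit-error class.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "Assay",
    "SampleType",
    "ChemicalRecord",
    "MeasurementRecord",
    "PipelineConfig",
    "SchemaError",
    "ValidationError",
    "MEASUREMENT_COLUMNS",
    "CHEMICAL_COLUMNS",
    "validate_measurements",
    "validate_chemicals",
    "records_to_frame",
]


class SchemaError(ValueError):
    """A required column is missing or has an unusable dtype."""


class ValidationError(ValueError):
    """One or more rows violate a table invariant; message names the rows."""


class Assay(str, enum.Enum):
    """Which laboratory assay a measurement belongs to."""

    UC_PPB = "uc_ppb"
    HEP_CLEARANCE = "hep_clearance"
    CALIBRATION = "calibration"


class SampleType(str, enum.Enum):
    """Role of the sample within its assay."""

    STANDARD = "standard"
    BLANK = "blank"
    T1HR = "T1hr"
    T5HR = "T5hr"
    AF = "AF"
    HEP_CELLS = "hep_cells"
    CELLFREE = "cellfree_ctrl"
    INACTIVATED = "inactivated_ctrl"


#: columns of a valid measurements table, in canonical order
MEASUREMENT_COLUMNS = [
    "chem_id",
    "assay",
    "sample_type",
    "batch_id",
    "replicate",
    "time_min",
    "nominal_conc",
    "response_ratio",
    "below_detection",
]

#: columns of a valid chemicals table ("loec" and "rb" may be empty)
CHEMICAL_COLUMNS = [
    "chem_id",
    "name",
    "mol_weight",
    "category",
    "ionization_class",
    "loec",
    "rb",
]

_ASSAY_VALUES = {a.value for a in Assay}
_SAMPLE_VALUES = {s.value for s in SampleType}
_IONIZATION_VALUES = {"ionized", "neutral"}


@dataclass
class ChemicalRecord:
    """Chemical-level metadata.

    Parameters
    ----------
    chem_id : str
        Opaque identifier (e.g. a DTXSID string).
    name : str
        Human-readable name.
    mol_weight : float
        Molecular weight in g/mol; must be positive.
    category : str
        Functional-category label (e.g. ``"fluorotelomer alcohol"``);
        carried through as a passthrough field.
    ionization_class : str
        ``"ionized"`` or ``"neutral"`` at physiological pH.
    loec : float, optional
        Lowest-observed-effect concentration from an in vitro bioactivity
        screen, µM; must be positive when present.
    rb : float, optional
        Blood:plasma concentration ratio for this chemical. Required for
        neutral chemicals at the IVIVE stage; ionized chemicals fall back
        to the configured default.
    """

    chem_id: str
    name: str
    mol_weight: float
    category: str = ""
    ionization_class: str = "ionized"
    loec: Optional[float] = None
    rb: Optional[float] = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.mol_weight) or self.mol_weight <= 0:
            raise ValidationError(f"{self.chem_id}: mol_weight must be > 0")
        if self.ionization_class not in _IONIZATION_VALUES:
            raise ValidationError(
                f"{self.chem_id}: ionization_class must be one of {_IONIZATION_VALUES}"
            )
        if self.loec is not None and not self.loec > 0:
            raise ValidationError(f"{self.chem_id}: loec must be > 0 when present")
        if self.rb is not None and not self.rb > 0:
            raise ValidationError(f"{self.chem_id}: rb must be > 0 when present")


@dataclass
class MeasurementRecord:
    """A single MS response-ratio observation with its assay context."""

    chem_id: str
    assay: str
    sample_type: str
    batch_id: str
    replicate: int = 1
    time_min: Optional[float] = None
    nominal_conc: Optional[float] = None
    response_ratio: Optional[float] = None
    below_detection: bool = False

    def __post_init__(self) -> None:
        self.assay = Assay(self.assay).value
        self.sample_type = SampleType(self.sample_type).value
        if self.replicate < 1:
            raise ValidationError(f"{self.chem_id}: replicate must be >= 1")
        is_standard = self.sample_type == SampleType.STANDARD.value
        if is_standard and (self.nominal_conc is None or not self.nominal_conc > 0):
            raise ValidationError(
                f"{self.chem_id}: standards must carry a positive nominal_conc"
            )
        if not is_standard and self.nominal_conc is not None:
            raise ValidationError(
                f"{self.chem_id}: non-standard samples must not carry nominal_conc"
            )
        is_hep = self.assay == Assay.HEP_CLEARANCE.value
        if is_hep and self.time_min is None:
            raise ValidationError(f"{self.chem_id}: hep_clearance rows need time_min")
        if not is_hep and self.time_min is not None:
            raise ValidationError(f"{self.chem_id}: time_min only valid for hep_clearance")
        if self.time_min is not None and self.time_min < 0:
            raise ValidationError(f"{self.chem_id}: time_min must be >= 0")
        if self.below_detection:
            self.response_ratio = None
        elif self.response_ratio is None or not (self.response_ratio >= 0):
            raise ValidationError(
                f"{self.chem_id}: response_ratio must be >= 0 unless below detection"
            )


@dataclass
class PipelineConfig:
    """Tunable thresholds and scalars used by :func:`invitrotk.pipeline.run_pipeline`.

    Defaults implement the study rules: depletion-slope F-test at
    ``alpha_ftest`` = 0.05, plasma-stability exclusion at strictly more than
    60% loss over the assay, and abiotic exclusion at 50% or more cell-free
    loss by 120 min.
    """

    alpha_ftest: float = 0.05
    plasma_loss_cutoff: float = 0.60
    abiotic_loss_cutoff: float = 0.50
    abiotic_check_time: float = 120.0
    run_bayes: bool = False
    #: keyword overrides for :class:`invitrotk.bayes.BayesConfig`
    bayes_options: dict = field(default_factory=dict)
    #: keyword overrides for :class:`invitrotk.ivive.IVIVEParams`
    ivive_options: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha_ftest", "plasma_loss_cutoff", "abiotic_loss_cutoff"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValidationError(f"{name} must lie in (0, 1), got {v}")
        if self.abiotic_check_time <= 0:
            raise ValidationError("abiotic_check_time must be > 0")


def _require_columns(df: pd.DataFrame, required: list[str], table: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{table} table is missing column(s): {', '.join(missing)}")


def validate_measurements(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and canonicalise a measurements table.

    Returns a copy with canonical column order and dtypes. Raises
    :class:`ValidationError` naming the offending row indices, or
    :class:`SchemaError` if columns are missing.
    """
    required = [c for c in MEASUREMENT_COLUMNS if c not in ("below_detection",)]
    _require_columns(df, required, "measurements")
    out = df.copy()
    if "below_detection" not in out.columns:
        out["below_detection"] = False
    out["below_detection"] = out["below_detection"].fillna(False).astype(bool)
    for col in ("time_min", "nominal_conc", "response_ratio"):
        try:
            out[col] = pd.to_numeric(out[col])
        except (ValueError, TypeError) as exc:
            bad = out.index[pd.to_numeric(out[col], errors="coerce").isna() & out[col].notna()]
            raise ValidationError(
                f"measurements: non-numeric {col} in row(s) {list(bad)[:10]}"
            ) from exc
    out["replicate"] = out["replicate"].astype(int)

    problems: list[str] = []

    def _flag(mask: pd.Series, msg: str) -> None:
        if mask.any():
            problems.append(f"{msg}: rows {list(out.index[mask])[:10]}")

    _flag(~out["assay"].isin(_ASSAY_VALUES), "unknown assay")
    _flag(~out["sample_type"].isin(_SAMPLE_VALUES), "unknown sample_type")
    _flag(out["replicate"] < 1, "replicate < 1")
    is_std = out["sample_type"] == SampleType.STANDARD.value
    _flag(is_std & ~(out["nominal_conc"] > 0), "standard without positive nominal_conc")
    _flag(~is_std & out["nominal_conc"].notna(), "nominal_conc on non-standard sample")
    is_hep = out["assay"] == Assay.HEP_CLEARANCE.value
    _flag(is_hep & out["time_min"].isna(), "hep_clearance row without time_min")
    _flag(~is_hep & out["time_min"].notna(), "time_min outside hep_clearance assay")
    _flag(out["time_min"] < 0, "negative time_min")
    observed = ~out["below_detection"]
    _flag(observed & ~(out["response_ratio"] >= 0), "response_ratio missing or negative")
    if problems:
        raise ValidationError("invalid measurements — " + "; ".join(problems))
    out.loc[out["below_detection"], "response_ratio"] = np.nan
    return out[MEASUREMENT_COLUMNS]


def validate_chemicals(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and canonicalise a chemicals table (see :class:`ChemicalRecord`)."""
    _require_columns(df, ["chem_id", "name", "mol_weight"], "chemicals")
    out = df.copy()
    for col, default in (
        ("category", ""),
        ("ionization_class", "ionized"),
        ("loec", np.nan),
        ("rb", np.nan),
    ):
        if col not in out.columns:
            out[col] = default
    for col in ("mol_weight", "loec", "rb"):
        out[col] = pd.to_numeric(out[col])
    problems = []
    if (~(out["mol_weight"] > 0)).any():
        problems.append(f"non-positive mol_weight: rows {list(out.index[~(out['mol_weight'] > 0)])}")
    bad_loec = out["loec"].notna() & ~(out["loec"] > 0)
    if bad_loec.any():
        problems.append(f"non-positive loec: rows {list(out.index[bad_loec])}")
    bad_ion = ~out["ionization_class"].isin(_IONIZATION_VALUES)
    if bad_ion.any():
        problems.append(f"unknown ionization_class: rows {list(out.index[bad_ion])}")
    if out["chem_id"].duplicated().any():
        problems.append("duplicate chem_id")
    if problems:
        raise ValidationError("invalid chemicals — " + "; ".join(problems))
    return out[CHEMICAL_COLUMNS]


def records_to_frame(records) -> pd.DataFrame:
    """Assemble validated :class:`MeasurementRecord` objects into a table."""
    rows = [
        {
            "chem_id": r.chem_id,
            "assay": r.assay,
            "sample_type": r.sample_type,
            "batch_id": r.batch_id,
            "replicate": r.replicate,
            "time_min": np.nan if r.time_min is None else r.time_min,
            "nominal_conc": np.nan if r.nominal_conc is None else r.nominal_conc,
            "response_ratio": np.nan if r.response_ratio is None else r.response_ratio,
            "below_detection": r.below_detection,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
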