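import numpy as np
import pandas as pd
import pytest

from invitrotk.synthetic import (
    ChemicalTruth,
    GeneratorSpec,
    NoiseSpec,
)


@pytest.fixture
def noiseless_spec() -> GeneratorSpec:
    """Generator with every noise source off: estimators must hit truth exactly."""
    return GeneratorSpec(noise=NoiseSpec(sigma0=0.0, cv=0.0, pipette_sdlog=0.0))


@pytest.fixture
def default_spec() -> GeneratorSpec:
    """Study-condition generator (10% proportional cv, small floor, 5% pipetting)."""
    return GeneratorSpec()


@pytest.fixture
def simple_chem() -> ChemicalTruth:
    return ChemicalTruth(
        "CHEM1", true_fup=0.1, true_k_met=0.01, true_k_bg=0.0, mol_weight=250.0, loec=2.0
    )


def linear_standards(
    slope: float = 0.002,
    intercept: float = 0.0,
    levels=None,
    chem_id: str = "C1",
    batch_id: str = "B1",
) -> pd.DataFrame:
    """Exact (noiseless) standards on a straight line."""
    if levels is None:
        levels = np.geomspace(1.75, 1250.0, 15)
    levels = np.asarray(levels, dtype=float)
    return pd.DataFrame(
        {
            "chem_id": chem_id,
            "batch_id": batch_id,
            "nominal_conc": levels,
            "response_ratio": intercept + slope * levels,
            "below_detection": False,
        }
    )
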