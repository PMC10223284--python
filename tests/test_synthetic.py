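"""Generator contracts: determinism, schema validity, closed loops."""

from dataclasses import replace

import numpy as np
import pytest

from invitrotk.clearance import abiotic_exclusion
from invitrotk.datamodel import validate_measurements
from invitrotk.io import write_table
from invitrotk.pipeline import run_pipeline
from invitrotk.ppb import plasma_stability_screen
from invitrotk.synthetic import (
    ChemicalTruth,
    GeneratorSpec,
    NoiseSpec,
    generate_calibration,
    generate_chemical_bundle,
    generate_cohort,
    generate_depletion,
    generate_uc_assay,
)


class TestCalibrationGenerator:
    def test_noiseless_responses_on_curve(self, noiseless_spec):
        df = generate_calibration(noiseless_spec, "X", "b1")
        std = df[df.sample_type == "standard"]
        expected = noiseless_spec.calibration_truth.response(std.nominal_conc)
        np.testing.assert_allclose(std.response_ratio, expected, rtol=1e-12)

    def test_default_levels_span_stated_range(self, default_spec):
        df = generate_calibration(default_spec, "X", "b1")
        levels = df[df.sample_type == "standard"].nominal_conc
        assert levels.min() == pytest.approx(1.75)
        assert levels.max() == pytest.approx(1250.0)
        assert levels.nunique() == 15
        hep = generate_calibration(default_spec, "X", "h1", default_spec.hepatocyte_calibration)
        hl = hep[hep.sample_type == "standard"].nominal_conc
        assert (hl.min(), hl.max()) == (pytest.approx(7.0), pytest.approx(5000.0))

    def test_seeded_determinism(self, default_spec, tmp_path):
        a = generate_calibration(default_spec, "X", "b1")
        b = generate_calibration(default_spec, "X", "b1")
        write_table(a, tmp_path / "a.csv")
        write_table(b, tmp_path / "b.csv")
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()


class TestUCGenerator:
    def test_noiseless_closed_loop(self, noiseless_spec):
        chem = ChemicalTruth("X", true_fup=0.1)
        res = run_pipeline(generate_chemical_bundle(noiseless_spec, chem))
        assert res.results.fup.iloc[0] == pytest.approx(0.1, rel=1e-10)

    def test_degradation_triggers_stability_exclusion(self, noiseless_spec):
        chem = ChemicalTruth("X", true_fup=0.1, true_degradation=0.3)  # 70% loss
        uc = generate_uc_assay(noiseless_spec, chem, "b1")
        truth = noiseless_spec.calibration_truth
        conc = (uc.set_index("sample_type").response_ratio - truth.beta0) / truth.beta1
        _, excluded = plasma_stability_screen(conc.loc["T1hr"], conc.loc["T5hr"])
        assert excluded

    def test_fully_unbound_chemical_has_af_equal_t5(self, noiseless_spec):
        chem = ChemicalTruth("X", true_fup=1.0)
        uc = generate_uc_assay(noiseless_spec, chem, "b1")
        by = uc.groupby("sample_type").response_ratio.mean()
        assert by["AF"] == pytest.approx(by["T5hr"], rel=1e-12)


class TestDepletionGenerator:
    def test_noiseless_closed_loop_recovers_clint(self, noiseless_spec):
        chem = ChemicalTruth("X", true_k_met=0.01, true_k_bg=0.0)
        res = run_pipeline(generate_chemical_bundle(noiseless_spec, chem))
        assert res.results.clint.iloc[0] == pytest.approx(20.0, rel=1e-9)

    def test_background_rate_near_abiotic_boundary(self, noiseless_spec):
        """k_bg = 0.0058/min leaves ~49.9% remaining at 120 min, just past
        the inclusive 50%-loss boundary."""
        chem = ChemicalTruth("X", true_k_met=0.0, true_k_bg=0.0058)
        dep = generate_depletion(noiseless_spec, chem, "h1")
        truth = noiseless_spec.calibration_truth
        cf = dep[dep.sample_type == "cellfree_ctrl"].copy()
        cf["conc"] = (cf.response_ratio - truth.beta0) / truth.beta1
        assert np.exp(-0.0058 * 120.0) == pytest.approx(0.4986, abs=1e-4)
        assert abiotic_exclusion(cf) is True

    def test_controls_decay_at_background_rate_only(self, noiseless_spec):
        chem = ChemicalTruth("X", true_k_met=0.02, true_k_bg=0.004)
        dep = generate_depletion(noiseless_spec, chem, "h1")
        for stype, k in (("hep_cells", 0.024), ("cellfree_ctrl", 0.004),
                         ("inactivated_ctrl", 0.004)):
            sub = dep[(dep.sample_type == stype) & (dep.replicate == 1)]
            slope = np.polyfit(sub.time_min, np.log(sub.response_ratio), 1)[0]
            assert slope == pytest.approx(-k, rel=1e-9)

    def test_same_seed_same_tables(self, default_spec):
        chem = ChemicalTruth("X", true_k_met=0.01)
        a = generate_depletion(default_spec, chem, "h1")
        b = generate_depletion(default_spec, chem, "h1")
        assert a.equals(b)


class TestCohort:
    def test_generated_tables_pass_validation(self):
        chemicals, truth, m = generate_cohort(4, seed=5)
        validate_measurements(m)  # raises on any invariant violation
        assert set(truth.chem_id) == set(chemicals.chem_id)
        assert m.chem_id.nunique() == 4

    def test_single_chemical_bundle(self):
        chemicals, truth, m = generate_cohort(1, seed=2)
        assert len(chemicals) == 1
        assert set(m.assay) == {"calibration", "uc_ppb", "hep_clearance"}

    def test_skewed_binding_distribution(self):
        _, truth, _ = generate_cohort(43, seed=9)
        assert truth.true_fup.median() < truth.true_fup.mean()

    def test_noise_collapse_recovers_truth_exactly(self):
        spec = GeneratorSpec(noise=NoiseSpec(sigma0=0.0, cv=0.0, pipette_sdlog=0.0))
        chemicals, truth, m = generate_cohort(3, seed=1, spec=spec)
        res = run_pipeline(m, chemicals)
        j = res.results.merge(truth, on="chem_id")
        np.testing.assert_allclose(j.fup, np.minimum(1.0, j.true_fup), rtol=1e-8)
        np.testing.assert_allclose(j.clint, j.true_clint, rtol=1e-6, atol=1e-8)


def test_censoring_marks_below_detection(default_spec):
    """Responses under the truth-implied detection threshold are flagged and
    blanked; a noiseless generator censors nothing."""
    chem = ChemicalTruth("X", true_k_met=0.03, true_k_bg=0.0)  # deep depletion
    dep = generate_depletion(default_spec, chem, "h1")
    assert dep.below_detection.any()
    assert dep.loc[dep.below_detection, "response_ratio"].isna().all()
    quiet = GeneratorSpec(noise=NoiseSpec(sigma0=0.0, cv=0.0, pipette_sdlog=0.0))
    assert not generate_depletion(quiet, chem, "h1").below_detection.any()
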