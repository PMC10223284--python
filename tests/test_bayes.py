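"""Bayesian measurement models, sampler, and convergence diagnostics."""

import warnings
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from invitrotk.bayes import (
    BayesConfig,
    ClearanceModel,
    GaussianToyModel,
    Priors,
    UCBindingModel,
    flag_uncertain,
    multivariate_psrf,
    potential_scale_reduction,
    run_mcmc,
)
from invitrotk.synthetic import (
    ChemicalTruth,
    GeneratorSpec,
    NoiseSpec,
    generate_calibration,
    generate_depletion,
    generate_uc_assay,
)

FAST = dict(
    n_chains=3,
    burn_in=500,
    iterations_per_extension=2000,
    samples_per_chain_after_thinning=500,
    max_extensions=2,
)


def _uc_case(true_fup=0.1, cv=0.10, sigma0=0.0005, seed=0, n_reps=3, degradation=1.0):
    spec = GeneratorSpec(
        seed=seed, noise=NoiseSpec(sigma0=sigma0, cv=cv, pipette_sdlog=0.05)
    )
    spec.uc_design.n_replicates = n_reps
    chem = ChemicalTruth("X", true_fup=true_fup, true_degradation=degradation)
    std = generate_calibration(spec, "X", "b1")
    uc = generate_uc_assay(spec, chem, "b1")
    return UCBindingModel(
        std[std.sample_type == "standard"], uc,
        censor_limit=spec.censor_limit_nM() or None, chem_id="X",
    )


def _clearance_case(k_met, k_bg, cv=0.10, seed=0):
    spec = GeneratorSpec(seed=seed, noise=NoiseSpec(sigma0=0.0005, cv=cv, pipette_sdlog=0.05))
    chem = ChemicalTruth("X", true_k_met=k_met, true_k_bg=k_bg)
    std = generate_calibration(spec, "X", "h1", spec.hepatocyte_calibration)
    dep = generate_depletion(spec, chem, "h1")
    return ClearanceModel(
        std[std.sample_type == "standard"], dep,
        censor_limit=spec.censor_limit_nM() or None, chem_id="X",
    )


def _run(model, seed=1, **overrides):
    cfg = BayesConfig(seed=seed, **{**FAST, **overrides})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_mcmc(model, cfg)


class TestDiagnostics:
    def test_identical_chains_have_shrink_exactly_one(self):
        rng = np.random.default_rng(0)
        draws = rng.standard_normal(200)
        chains = np.stack([draws, draws, draws])
        assert potential_scale_reduction(chains) == 1.0
        multi = np.stack([np.column_stack([draws, 2 * draws])] * 4)
        assert multivariate_psrf(multi) == 1.0

    def test_disjoint_chains_have_large_shrink(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.0, 1.0, 300)
        b = rng.normal(10.0, 1.0, 300)
        assert potential_scale_reduction(np.stack([a, b])) > 3.0
        assert multivariate_psrf(np.stack([a[:, None], b[:, None]])) > 3.0

    def test_constant_parameter_is_ignored(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((3, 100))
        const = np.ones((3, 100))
        r = multivariate_psrf(np.stack([x, const], axis=2))
        assert np.isfinite(r) and r < 1.5


class TestFlagUncertain:
    def test_three_orders_of_magnitude_rule(self):
        assert not flag_uncertain(0.001, 0.9)      # 900-fold
        assert flag_uncertain(0.0001, 0.9)         # 9000-fold
        assert not flag_uncertain(0.0, 0.0005)     # floored lower bound

    @given(x=st.floats(1e-6, 1e3))
    @settings(max_examples=30, deadline=None)
    def test_scale_invariance(self, x):
        assert flag_uncertain(x, 1000.01 * x)
        assert not flag_uncertain(x, 999.9 * x)


class TestSamplerProtocol:
    def test_capped_extensions_report_nonconvergence(self):
        class BimodalModel(GaussianToyModel):
            def log_post(self, theta):
                x = theta[0]
                return float(
                    np.logaddexp(-0.5 * (x - 30.0) ** 2, -0.5 * (x + 30.0) ** 2)
                )

        model = BimodalModel()
        with pytest.warns(UserWarning, match="not converged"):
            res = run_mcmc(
                model,
                BayesConfig(
                    n_chains=4, burn_in=200, iterations_per_extension=500,
                    samples_per_chain_after_thinning=250, max_extensions=2, seed=3,
                ),
            )
        assert not res.converged
        assert res.n_extensions == 2
        assert res.summaries  # summaries still emitted

    def test_extension_loop_stops_at_convergence(self):
        res = _run(GaussianToyModel(), seed=4, max_extensions=5)
        assert res.converged
        assert res.n_extensions < 5
        assert res.shrink_factor < 1.05


class TestUCModel:
    def test_low_noise_limit_concentrates_on_truth(self):
        res = _run(_uc_case(true_fup=0.1, cv=0.005, sigma0=1e-5, seed=5), seed=5)
        s = res["fup"]
        assert s.median == pytest.approx(0.1, rel=0.01)
        noisy = _run(_uc_case(true_fup=0.1, cv=0.10, seed=5), seed=5)
        assert (s.ci_upper - s.ci_lower) < (
            noisy["fup"].ci_upper - noisy["fup"].ci_lower
        )

    def test_null_degradation_posterior_near_one(self):
        res = _run(_uc_case(true_fup=0.3, degradation=1.0, seed=6), seed=6)
        assert res["degradation"].median > 0.85

    def test_posterior_respects_unit_interval_support(self):
        res = _run(_uc_case(seed=7), seed=7)
        assert np.all((res.samples["fup"] > 0) & (res.samples["fup"] < 1))
        assert np.all((res.samples["degradation"] > 0) & (res.samples["degradation"] <= 1))

    def test_agrees_with_point_estimator_at_low_noise(self):
        """Cross-module oracle: at cv <= 5% the posterior median and the
        ratio-of-means point estimate coincide within 10%."""
        from invitrotk.pipeline import run_pipeline
        from invitrotk.synthetic import generate_chemical_bundle

        spec = GeneratorSpec(seed=8, noise=NoiseSpec(sigma0=2e-4, cv=0.05, pipette_sdlog=0.02))
        chem = ChemicalTruth("X", true_fup=0.2)
        m = generate_chemical_bundle(spec, chem)
        point = run_pipeline(m).results.fup.iloc[0]
        model = _uc_case(true_fup=0.2, cv=0.05, sigma0=2e-4, seed=8)
        res = _run(model, seed=8)
        assert res["fup"].median == pytest.approx(point, rel=0.10)

    def test_prior_sensitivity_is_mild_on_informative_data(self):
        std_uc = _uc_case(true_fup=0.1, seed=9)
        base = _run(std_uc, seed=9)["fup"].median
        wide = replace(
            std_uc.priors, conc_sdlog=0.6, nu_scale=0.4, sigma0_scale=0.01
        )
        alt_model = _uc_case(true_fup=0.1, seed=9)
        alt_model.priors = wide
        alt = _run(alt_model, seed=9)["fup"].median
        assert alt == pytest.approx(base, rel=0.15)

    def test_build_errors(self):
        spec = GeneratorSpec(seed=10)
        std = generate_calibration(spec, "X", "OTHER_BATCH")
        uc = generate_uc_assay(spec, ChemicalTruth("X"), "b1")
        with pytest.raises(ValueError, match="no calibration standards"):
            UCBindingModel(std[std.sample_type == "standard"], uc, chem_id="X")

    def test_doubling_replicates_does_not_widen_interval(self):
        """Monte-Carlo monotonicity: six replicate experiments give a median
        CI no more than 5% wider than three."""
        widths = {3: [], 6: []}
        for seed in range(10):
            for n in (3, 6):
                res = _run(
                    _uc_case(seed=100 + seed, n_reps=n), seed=seed,
                    n_chains=2, burn_in=400, iterations_per_extension=1200,
                    samples_per_chain_after_thinning=400, max_extensions=1,
                )
                s = res["fup"]
                widths[n].append(s.ci_upper - s.ci_lower)
        assert np.median(widths[6]) <= 1.05 * np.median(widths[3])


class TestClearanceModel:
    def test_recovery_of_known_clearance(self):
        res = _run(_clearance_case(k_met=0.01, k_bg=0.0, seed=11), seed=11)
        assert res["clint"].median == pytest.approx(20.0, rel=0.15)

    def test_null_clearance_concentrates_near_zero(self):
        res = _run(_clearance_case(k_met=0.0, k_bg=0.002, seed=12), seed=12)
        assert np.mean(res.samples["clint"] > 5.0) < 0.1

    def test_background_loss_not_attributed_to_metabolism(self):
        """Large total loss driven entirely by abiotic degradation leaves the
        metabolic clearance posterior near zero."""
        res = _run(_clearance_case(k_met=0.0, k_bg=0.004, seed=13), seed=13)
        assert np.mean(res.samples["clint"] > 5.0) < 0.1
        assert res["k_bg"].median == pytest.approx(0.004, rel=0.25)
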