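"""Hierarchical Bayesian measurement-error models for the TK assays.

Point estimates of f_up and Cl_int ignore how calibration noise propagates
into the derived quantities. The models here describe the measurement
process jointly:

1. A per-batch calibration sub-model. The observed response ratio is
   ``y ~ Normal(mu, sigma(mu))`` with ``mu = b0 + b1·C`` and heteroscedastic
   ``sigma(mu) = sqrt(sigma0² + (nu·mu)²)`` — a constant floor plus a
   proportional component. When a chemical was measured on several days,
   each day (batch) has its own calibration coefficients.
2. An assay sub-model. For the ultracentrifugation assay, each replicate
   carries a latent T1hr concentration (lognormal around the nominal
   at-instrument level), a shared degradation factor ``D ∈ (0, 1]`` gives
   ``C_T5 = D·C_T1``, and a single fraction unbound ``fup ~ Uniform(0, 1)``
   gives ``C_AF = fup·C_T5``. For the depletion assay, the whole-cell series
   decays at ``k_met + k_bg`` and the cell-free series at ``k_bg``, both
   rate constants with half-Normal priors; ``Cl_int = 2000·k_met`` is a
   derived parameter.
3. Left-censoring: responses flagged below detection contribute
   ``P(y < threshold)`` rather than a density term.

Sampling uses blockwise adaptive random-walk Metropolis over several
independent chains. Following the study protocol, chains are repeatedly
extended (each extension = burn-in + sampling iterations thinned to a fixed
number of draws) until the Brooks–Gelman multivariate shrink factor over
the monitored parameters drops below 1.05; summaries (median and central
95% credible interval) come from the pooled post-convergence draws.
Estimates whose 95% interval spans more than three orders of magnitude are
flagged as uncertain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.special import expit, log_ndtr

__all__ = [
    "BayesConfig",
    "Priors",
    "PosteriorSummary",
    "McmcResult",
    "UCBindingModel",
    "ClearanceModel",
    "GaussianToyModel",
    "build_uc_model",
    "build_clearance_model",
    "run_mcmc",
    "flag_uncertain",
    "potential_scale_reduction",
    "multivariate_psrf",
]

_LOG_2_PI = float(np.log(2.0 * np.pi))


@dataclass
class BayesConfig:
    """MCMC protocol settings.

    Defaults mirror the study protocol: 5 chains, 50,000-iteration burn-in
    followed by 50,000 iterations thinned to 2,000 samples per chain per
    extension, extended until the multivariate shrink factor is below 1.05
    (10,000 pooled samples at convergence).
    """

    n_chains: int = 5
    burn_in: int = 50_000
    iterations_per_extension: int = 50_000
    samples_per_chain_after_thinning: int = 2_000
    shrink_threshold: float = 1.05
    max_extensions: int = 5
    seed: int = 0
    init_jitter: float = 0.5
    max_init_tries: int = 20

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("n_chains must be >= 2 (shrink factor needs several chains)")
        if not self.shrink_threshold > 1:
            raise ValueError("shrink_threshold must be > 1")


@dataclass
class Priors:
    """Prior hyperparameters (all configurable; see docs/methods.md).

    f_up and the degradation factor D are uniform on (0, 1); latent
    log-concentrations are Normal around the nominal with sd
    ``conc_sdlog``; the noise floor and proportional cv get half-Cauchy
    priors; depletion rate constants get half-Normal priors.
    """

    conc_sdlog: float = 0.3
    sigma0_scale: float = 0.005
    nu_scale: float = 0.2
    k_scale: float = 0.05        # 1/min, half-Normal sd for rate constants
    intercept_sd: float = 1.0    # response-ratio units
    slope_sdlog: float = 3.0     # sd of log-slope around its least-squares value


@dataclass
class PosteriorSummary:
    """Median and 95% credible interval for one parameter of one chemical."""

    chem_id: str
    parameter: str
    median: float
    ci_lower: float
    ci_upper: float
    n_samples: int
    shrink_factor: float
    converged: bool
    uncertain: bool


@dataclass
class McmcResult:
    """Output of :func:`run_mcmc`: summaries plus pooled and per-chain draws."""

    summaries: list
    samples: dict
    chain_samples: dict
    shrink_factor: float
    converged: bool
    n_extensions: int

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.summaries])

    def __getitem__(self, parameter: str) -> PosteriorSummary:
        for s in self.summaries:
            if s.parameter == parameter:
                return s
        raise KeyError(parameter)


def flag_uncertain(
    ci_lower: float, ci_upper: float, ratio: float = 1e3, floor: float = 1e-6
) -> bool:
    """True iff a credible interval for a positive parameter spans more than
    ``ratio`` (default three orders of magnitude). Non-positive lower bounds
    are evaluated at ``floor``."""
    lo = ci_lower if ci_lower > 0 else floor
    return bool(ci_upper / lo > ratio)


# ---------------------------------------------------------------------------
# convergence diagnostics


def potential_scale_reduction(chains) -> float:
    """Univariate potential scale reduction factor (Gelman–Rubin R-hat).

    ``chains`` has shape (m chains, n draws). Identical chains give exactly
    1 (the between-chain term vanishes and the diagnostic is floored at 1,
    its asymptotic value).
    """
    x = np.asarray(chains, dtype=float)
    m, n = x.shape
    means = x.mean(axis=1)
    w = x.var(axis=1, ddof=1).mean() if n > 1 else 0.0
    b_over_n = means.var(ddof=1)
    scale = max(np.abs(x).max(), 1.0)
    if b_over_n <= (1e-13 * scale) ** 2:
        return 1.0
    if w <= (1e-13 * scale) ** 2:
        return float("inf")
    v_hat = (n - 1) / n * w + (1.0 + 1.0 / m) * b_over_n
    return float(max(1.0, np.sqrt(v_hat / w)))


def multivariate_psrf(chains) -> float:
    """Brooks–Gelman multivariate shrink factor.

    ``chains`` has shape (m chains, n draws, p parameters). Computed as
    ``sqrt((n−1)/n + (m+1)/m · λ₁)`` with λ₁ the largest eigenvalue of
    ``W⁻¹ B/n``; constant parameters are dropped, and identical chains give
    exactly 1.
    """
    x = np.asarray(chains, dtype=float)
    m, n, _ = x.shape
    keep = x.reshape(m * n, -1).var(axis=0) > 0
    if not keep.any():
        return 1.0
    x = x[:, :, keep]
    p = x.shape[2]
    means = x.mean(axis=1)                      # (m, p)
    w = np.zeros((p, p))
    for c in range(m):
        w += np.cov(x[c].T, ddof=1).reshape(p, p)
    w /= m
    b_over_n = np.cov(means.T, ddof=1).reshape(p, p)
    scale = np.trace(w) + np.trace(b_over_n)
    if np.trace(b_over_n) <= 1e-26 * max(scale, 1.0):
        return 1.0
    # symmetric-definite generalized eigenproblem; ridge guards singular W
    ridge = 1e-12 * max(np.trace(w) / p, 1e-300)
    lam = eigh(b_over_n, w + ridge * np.eye(p), eigvals_only=True)[-1]
    return float(max(1.0, np.sqrt((n - 1) / n + (m + 1) / m * lam)))


# ---------------------------------------------------------------------------
# priors shared by both assay models


def _log_half_cauchy(x: float, scale: float) -> float:
    return float(np.log(2.0 / np.pi) - np.log(scale) - np.log1p((x / scale) ** 2))


def _normal_loglik(y, mu, sigma):
    return -np.log(sigma) - 0.5 * ((y - mu) / sigma) ** 2 - 0.5 * _LOG_2_PI


class _AssayModel:
    """Shared machinery: per-batch calibration data and noise priors."""

    #: parameters summarised/monitored; subclasses override
    monitored = ()
    positive_params = ()

    def __init__(self, standards: pd.DataFrame, priors: Priors, chem_id: str):
        self.priors = priors
        self.chem_id = chem_id
        self.batches = sorted(standards["batch_id"].astype(str).unique())
        if not self.batches:
            raise ValueError(f"{chem_id}: no calibration standards supplied")
        self._batch_index = {b: i for i, b in enumerate(self.batches)}
        std = standards.dropna(subset=["nominal_conc"])
        obs = std[~std["below_detection"].astype(bool)]
        self._std_conc = obs["nominal_conc"].to_numpy(float)
        self._std_y = obs["response_ratio"].to_numpy(float)
        self._std_batch = obs["batch_id"].astype(str).map(self._batch_index).to_numpy(int)
        # least-squares initial calibration per batch anchors the slope prior
        self._b0_init = np.zeros(len(self.batches))
        self._lb1_init = np.zeros(len(self.batches))
        for b, i in self._batch_index.items():
            sel = self._std_batch == i
            if sel.sum() < 2:
                raise ValueError(f"{chem_id}: batch {b} has fewer than 2 usable standards")
            X = np.vander(self._std_conc[sel], 2, increasing=True)
            beta, *_ = np.linalg.lstsq(X, self._std_y[sel], rcond=None)
            self._b0_init[i] = beta[0]
            self._lb1_init[i] = np.log(max(beta[1], 1e-8))
        self.n_batches = len(self.batches)

    # subclasses provide: dim, blocks, base_widths, initial, log_post, constrain

    def _cal_prior(self, b0, lb1, s0, nu, ls0, lnu) -> float:
        pri = self.priors
        lp = float(-0.5 * np.sum((b0 / pri.intercept_sd) ** 2))
        lp += float(-0.5 * np.sum(((lb1 - self._lb1_init) / pri.slope_sdlog) ** 2))
        lp += _log_half_cauchy(s0, pri.sigma0_scale) + ls0
        lp += _log_half_cauchy(nu, pri.nu_scale) + lnu
        return lp

    def _loglik(self, y, mu, s0, nu, censored=None, thr=None) -> float:
        sigma = np.sqrt(s0 * s0 + (nu * mu) ** 2)
        if censored is None or not censored.any():
            return float(np.sum(_normal_loglik(y, mu, sigma)))
        obs = ~censored
        ll = float(np.sum(_normal_loglik(y[obs], mu[obs], sigma[obs])))
        ll += float(np.sum(log_ndtr((thr[censored] - mu[censored]) / sigma[censored])))
        return ll


class UCBindingModel(_AssayModel):
    """Joint calibration + ultracentrifugation-assay model for one chemical.

    Parameters
    ----------
    standards : pandas.DataFrame
        Calibration standards (``batch_id``, ``nominal_conc``,
        ``response_ratio``, ``below_detection``) for every batch in which
        assay samples were measured.
    uc_samples : pandas.DataFrame
        UC assay rows (``batch_id``, ``sample_type`` in
        {T1hr, T5hr, AF}, ``replicate``, ``response_ratio``,
        ``below_detection``).
    nominal_conc : float
        Nominal at-instrument T1hr concentration (nM); default 250 nM
        (10 µM assay concentration through the plasma work-up dilution).
    censor_limit : float, optional
        Concentration (nM) below which responses were reported as
        below-detection; required if any sample is censored.
    """

    monitored = ("fup", "degradation", "sigma0", "nu")
    positive_params = ("fup", "degradation", "sigma0", "nu")
    _KIND = {"T1hr": 0, "T5hr": 1, "AF": 2}

    def __init__(
        self,
        standards: pd.DataFrame,
        uc_samples: pd.DataFrame,
        nominal_conc: float = 250.0,
        censor_limit: Optional[float] = None,
        priors: Priors = Priors(),
        chem_id: str = "",
    ):
        super().__init__(standards, priors, chem_id)
        uc = uc_samples[uc_samples["sample_type"].isin(self._KIND)].copy()
        if uc.empty:
            raise ValueError(f"{chem_id}: no UC assay samples")
        missing = set(uc["batch_id"].astype(str)) - set(self.batches)
        if missing:
            raise ValueError(
                f"{chem_id}: assay batch(es) {sorted(missing)} have no calibration standards"
            )
        pairs = sorted(set(zip(uc["batch_id"].astype(str), uc["replicate"].astype(int))))
        self._rep_index = {p: i for i, p in enumerate(pairs)}
        self.n_reps = len(pairs)
        self._uc_rep = np.array(
            [self._rep_index[(b, r)] for b, r in zip(uc["batch_id"].astype(str), uc["replicate"].astype(int))]
        )
        self._uc_kind = uc["sample_type"].map(self._KIND).to_numpy(int)
        self._uc_is_t5 = self._uc_kind == 1
        self._uc_is_af = self._uc_kind == 2
        self._uc_batch = uc["batch_id"].astype(str).map(self._batch_index).to_numpy(int)
        self._uc_y = uc["response_ratio"].to_numpy(float)
        self._uc_cens = uc["below_detection"].to_numpy(bool)
        if self._uc_cens.any() and censor_limit is None:
            raise ValueError(f"{chem_id}: censored samples present but no censor_limit given")
        self.censor_limit = censor_limit
        self.log_nominal = float(np.log(nominal_conc))
        # fused observation vector (standards prefix + assay samples) so the
        # likelihood is one vectorised pass
        n_std = self._std_conc.size
        self._n_std = n_std
        self._y_all = np.concatenate([self._std_y, np.where(self._uc_cens, 0.0, self._uc_y)])
        self._batch_all = np.concatenate([self._std_batch, self._uc_batch])
        self._cens_all = np.concatenate(
            [np.zeros(n_std, dtype=bool), self._uc_cens]
        )
        self._obs_all = ~self._cens_all
        self._any_cens = bool(self._cens_all.any())
        self._conc_buf = np.empty(self._y_all.size)
        self._conc_buf[:n_std] = self._std_conc
        nb = self.n_batches
        self.dim = 2 * nb + 2 + self.n_reps + 2
        self._sl_cal = slice(0, 2 * nb)
        self._i_ls0 = 2 * nb
        self._i_lnu = 2 * nb + 1
        self._sl_z = slice(2 * nb + 2, 2 * nb + 2 + self.n_reps)
        self._i_d = self.dim - 2
        self._i_f = self.dim - 1
        self.blocks = [
            np.arange(2 * nb),
            np.array([self._i_ls0, self._i_lnu]),
            np.arange(self._sl_z.start, self._sl_z.stop),
            np.array([self._i_d, self._i_f]),
        ]
        w = np.empty(self.dim)
        w[self._sl_cal] = np.tile([0.002, 0.05], nb)
        w[self._i_ls0] = w[self._i_lnu] = 0.2
        w[self._sl_z] = 0.05
        w[self._i_d] = w[self._i_f] = 0.3
        self.base_widths = w

    def initial(self, fup0: float = 0.3) -> np.ndarray:
        theta = np.empty(self.dim)
        theta[self._sl_cal] = np.column_stack([self._b0_init, self._lb1_init]).ravel()
        theta[self._i_ls0] = np.log(self.priors.sigma0_scale)
        theta[self._i_lnu] = np.log(0.1)
        theta[self._sl_z] = self.log_nominal
        theta[self._i_d] = _logit(0.9)
        theta[self._i_f] = _logit(np.clip(fup0, 0.01, 0.99))
        return theta

    def log_post(self, theta: np.ndarray) -> float:
        nb = self.n_batches
        cal = theta[self._sl_cal].reshape(nb, 2)
        b0 = cal[:, 0]
        lb1 = cal[:, 1]
        b1 = np.exp(lb1)
        ls0 = theta[self._i_ls0]
        lnu = theta[self._i_lnu]
        if ls0 < -30 or ls0 > 5 or lnu < -30 or lnu > 5 or np.any(np.abs(lb1) > 40):
            return -np.inf
        s0 = np.exp(ls0)
        nu = np.exp(lnu)
        z = theta[self._sl_z]
        d = theta[self._i_d]
        f = theta[self._i_f]
        D = expit(d)
        fup = expit(f)

        lp = self._cal_prior(b0, lb1, s0, nu, ls0, lnu)
        lp += float(-0.5 * np.sum(((z - self.log_nominal) / self.priors.conc_sdlog) ** 2))
        # uniform priors on D and fup with logit-transform Jacobians
        lp += float(np.log(D) + np.log1p(-D) + np.log(fup) + np.log1p(-fup))

        factor = np.where(self._uc_is_af, fup * D, np.where(self._uc_is_t5, D, 1.0))
        buf = self._conc_buf
        buf[self._n_std :] = np.exp(z)[self._uc_rep] * factor
        b0a = b0[self._batch_all]
        b1a = b1[self._batch_all]
        mu = b0a + b1a * buf
        sigma = np.sqrt(s0 * s0 + (nu * mu) ** 2)
        if not self._any_cens:
            r = (self._y_all - mu) / sigma
            lp += -np.log(sigma).sum() - 0.5 * float(r @ r) - 0.5 * _LOG_2_PI * r.size
        else:
            obs = self._obs_all
            cens = self._cens_all
            r = (self._y_all[obs] - mu[obs]) / sigma[obs]
            lp += -np.log(sigma[obs]).sum() - 0.5 * float(r @ r) - 0.5 * _LOG_2_PI * r.size
            thr = b0a[cens] + b1a[cens] * self.censor_limit
            lp += float(np.sum(log_ndtr((thr - mu[cens]) / sigma[cens])))
        return lp

    def constrain(self, thetas: np.ndarray) -> dict:
        return {
            "fup": expit(thetas[:, self._i_f]),
            "degradation": expit(thetas[:, self._i_d]),
            "sigma0": np.exp(thetas[:, self._i_ls0]),
            "nu": np.exp(thetas[:, self._i_lnu]),
        }


class ClearanceModel(_AssayModel):
    """Joint calibration + substrate-depletion model for one chemical.

    The whole-cell series decays at ``k_met + k_bg`` from a latent initial
    concentration; the cell-free series decays at ``k_bg``. Both rate
    constants carry half-Normal priors, so metabolic clearance is only
    attributed to the difference the data support. ``clint = 2000·k_met``
    is reported as a derived parameter.
    """

    monitored = ("clint", "k_bg", "sigma0", "nu")
    positive_params = ("clint", "k_met", "k_bg", "sigma0", "nu")

    def __init__(
        self,
        standards: pd.DataFrame,
        depletion_samples: pd.DataFrame,
        nominal_conc: float = 50.0,
        censor_limit: Optional[float] = None,
        priors: Priors = Priors(),
        chem_id: str = "",
        clint_scalar: float = 2000.0,
    ):
        super().__init__(standards, priors, chem_id)
        dep = depletion_samples[
            depletion_samples["sample_type"].isin(["hep_cells", "cellfree_ctrl"])
        ].copy()
        if not (dep["sample_type"] == "hep_cells").any():
            raise ValueError(f"{chem_id}: no whole-cell depletion series")
        if not (dep["sample_type"] == "cellfree_ctrl").any():
            raise ValueError(f"{chem_id}: no cell-free control series")
        missing = set(dep["batch_id"].astype(str)) - set(self.batches)
        if missing:
            raise ValueError(
                f"{chem_id}: assay batch(es) {sorted(missing)} have no calibration standards"
            )
        self._dep_cells = (dep["sample_type"] == "hep_cells").to_numpy(bool)
        self._dep_t = dep["time_min"].to_numpy(float)
        self._dep_batch = dep["batch_id"].astype(str).map(self._batch_index).to_numpy(int)
        self._dep_y = dep["response_ratio"].to_numpy(float)
        self._dep_cens = dep["below_detection"].to_numpy(bool)
        if self._dep_cens.any() and censor_limit is None:
            raise ValueError(f"{chem_id}: censored samples present but no censor_limit given")
        self.censor_limit = censor_limit
        self.log_nominal = float(np.log(nominal_conc))
        self.clint_scalar = clint_scalar
        nb = self.n_batches
        self.dim = 2 * nb + 2 + 2 + 2
        self._sl_cal = slice(0, 2 * nb)
        self._i_ls0 = 2 * nb
        self._i_lnu = 2 * nb + 1
        self._i_c0c = 2 * nb + 2
        self._i_c0f = 2 * nb + 3
        self._i_lkm = 2 * nb + 4
        self._i_lkb = 2 * nb + 5
        self.blocks = [
            np.arange(2 * nb),
            np.array([self._i_ls0, self._i_lnu]),
            np.array([self._i_c0c, self._i_c0f]),
            np.array([self._i_lkm, self._i_lkb]),
        ]
        w = np.empty(self.dim)
        w[self._sl_cal] = np.tile([0.002, 0.05], nb)
        w[self._i_ls0] = w[self._i_lnu] = 0.2
        w[self._i_c0c] = w[self._i_c0f] = 0.05
        w[self._i_lkm] = w[self._i_lkb] = 0.4
        self.base_widths = w

    def initial(self, k_met0: float = 0.005, k_bg0: float = 0.002) -> np.ndarray:
        theta = np.empty(self.dim)
        theta[self._sl_cal] = np.column_stack([self._b0_init, self._lb1_init]).ravel()
        theta[self._i_ls0] = np.log(self.priors.sigma0_scale)
        theta[self._i_lnu] = np.log(0.1)
        theta[self._i_c0c] = theta[self._i_c0f] = self.log_nominal
        theta[self._i_lkm] = np.log(max(k_met0, 1e-5))
        theta[self._i_lkb] = np.log(max(k_bg0, 1e-5))
        return theta

    def log_post(self, theta: np.ndarray) -> float:
        nb = self.n_batches
        cal = theta[self._sl_cal].reshape(nb, 2)
        b0 = cal[:, 0]
        lb1 = cal[:, 1]
        b1 = np.exp(lb1)
        ls0 = theta[self._i_ls0]
        lnu = theta[self._i_lnu]
        lkm = theta[self._i_lkm]
        lkb = theta[self._i_lkb]
        if (
            ls0 < -30 or ls0 > 5 or lnu < -30 or lnu > 5
            or lkm < -30 or lkm > 3 or lkb < -30 or lkb > 3
            or np.any(np.abs(lb1) > 40)
        ):
            return -np.inf
        s0 = np.exp(ls0)
        nu = np.exp(lnu)
        km = np.exp(lkm)
        kb = np.exp(lkb)
        c0c = theta[self._i_c0c]
        c0f = theta[self._i_c0f]

        pri = self.priors
        lp = self._cal_prior(b0, lb1, s0, nu, ls0, lnu)
        lp += -0.5 * ((c0c - self.log_nominal) / pri.conc_sdlog) ** 2
        lp += -0.5 * ((c0f - self.log_nominal) / pri.conc_sdlog) ** 2
        # half-Normal priors on the rate constants, log-scale Jacobian included
        lp += -0.5 * (km / pri.k_scale) ** 2 + lkm
        lp += -0.5 * (kb / pri.k_scale) ** 2 + lkb

        mu_std = b0[self._std_batch] + b1[self._std_batch] * self._std_conc
        lp += self._loglik(self._std_y, mu_std, s0, nu)

        logc = np.where(
            self._dep_cells,
            c0c - (km + kb) * self._dep_t,
            c0f - kb * self._dep_t,
        )
        mu_dep = b0[self._dep_batch] + b1[self._dep_batch] * np.exp(logc)
        thr = None
        if self.censor_limit is not None:
            thr = b0[self._dep_batch] + b1[self._dep_batch] * self.censor_limit
        lp += self._loglik(self._dep_y, mu_dep, s0, nu, self._dep_cens, thr)
        return float(lp)

    def constrain(self, thetas: np.ndarray) -> dict:
        km = np.exp(thetas[:, self._i_lkm])
        return {
            "k_met": km,
            "k_bg": np.exp(thetas[:, self._i_lkb]),
            "clint": self.clint_scalar * km,
            "sigma0": np.exp(thetas[:, self._i_ls0]),
            "nu": np.exp(thetas[:, self._i_lnu]),
        }


class GaussianToyModel:
    """Independent standard-Normal target; used to validate the sampler."""

    monitored = ("x",)
    positive_params = ()
    chem_id = "toy"

    def __init__(self, dim: int = 1):
        self.dim = dim
        self.blocks = [np.arange(dim)]
        self.base_widths = np.full(dim, 1.0)

    def initial(self) -> np.ndarray:
        return np.zeros(self.dim)

    def log_post(self, theta: np.ndarray) -> float:
        return float(-0.5 * np.sum(theta**2))

    def constrain(self, thetas: np.ndarray) -> dict:
        return {"x": thetas[:, 0]}


def _logit(p: float) -> float:
    return float(np.log(p) - np.log1p(-p))


def build_uc_model(standards, uc_samples, **kwargs) -> UCBindingModel:
    """Convenience constructor for :class:`UCBindingModel`."""
    return UCBindingModel(standards, uc_samples, **kwargs)


def build_clearance_model(standards, depletion_samples, **kwargs) -> ClearanceModel:
    """Convenience constructor for :class:`ClearanceModel`."""
    return ClearanceModel(standards, depletion_samples, **kwargs)


# ---------------------------------------------------------------------------
# sampler


def _run_chain(model, theta, scales, widths, n_burn, n_iter, n_keep, rng):
    """One extension of one chain: adaptive burn-in then thinned sampling."""
    logpost = model.log_post
    blocks = model.blocks
    lp = logpost(theta)
    # burn-in with Robbins–Monro scale adaptation toward ~30% acceptance
    history = np.empty((n_burn, theta.size)) if n_burn > 0 else None
    for i in range(n_burn):
        gamma = min(0.5, 1.0 / np.sqrt(1.0 + i))
        for k, idx in enumerate(blocks):
            prop = theta.copy()
            prop[idx] += scales[k] * widths[idx] * rng.standard_normal(idx.size)
            lp_new = logpost(prop)
            acc = lp_new - lp > np.log(rng.random()) if np.isfinite(lp_new) else False
            if acc:
                theta, lp = prop, lp_new
            scales[k] *= np.exp(gamma * ((1.0 if acc else 0.0) - 0.3))
        history[i] = theta
    if n_burn >= 200:
        # refresh per-component widths from the second half of burn-in
        sd = history[n_burn // 2 :].std(axis=0)
        widths = np.maximum(sd, 0.05 * model.base_widths)
    thin = max(1, n_iter // n_keep)
    kept = []
    for i in range(n_iter):
        for k, idx in enumerate(blocks):
            prop = theta.copy()
            prop[idx] += scales[k] * widths[idx] * rng.standard_normal(idx.size)
            lp_new = logpost(prop)
            if np.isfinite(lp_new) and lp_new - lp > np.log(rng.random()):
                theta, lp = prop, lp_new
        if (i + 1) % thin == 0:
            kept.append(theta.copy())
    return theta, np.array(kept), scales, widths


def run_mcmc(model, config: Optional[BayesConfig] = None) -> McmcResult:
    """Sample a model with the extension-until-converged protocol.

    Runs ``n_chains`` independent chains from jittered (overdispersed)
    starting points. Each extension performs a fresh adaptive burn-in
    followed by ``iterations_per_extension`` draws thinned to
    ``samples_per_chain_after_thinning``; after each extension the
    multivariate shrink factor over ``model.monitored`` is evaluated and
    chains are extended until it falls below ``shrink_threshold`` or
    ``max_extensions`` is reached (``converged`` reports which).
    Summaries always come from the final extension's pooled draws.
    """
    config = config or BayesConfig()
    root = np.random.default_rng(config.seed)
    chain_rngs = [np.random.default_rng(s) for s in root.spawn(config.n_chains)]

    center = model.initial()
    states = []
    for rng in chain_rngs:
        theta = None
        for _ in range(config.max_init_tries):
            cand = center + config.init_jitter * model.base_widths * rng.standard_normal(
                center.size
            )
            if np.isfinite(model.log_post(cand)):
                theta = cand
                break
        if theta is None:
            raise RuntimeError(
                f"{model.chem_id}: could not initialize a chain with finite log-density "
                f"after {config.max_init_tries} tries"
            )
        states.append(theta)
    scales = [np.ones(len(model.blocks)) for _ in range(config.n_chains)]
    widths = [model.base_widths.copy() for _ in range(config.n_chains)]

    converged = False
    n_ext = 0
    chain_draws: list[np.ndarray] = []
    shrink = np.inf
    while n_ext < config.max_extensions:
        n_ext += 1
        chain_draws = []
        for c, rng in enumerate(chain_rngs):
            states[c], draws, scales[c], widths[c] = _run_chain(
                model,
                states[c],
                scales[c],
                widths[c],
                config.burn_in,
                config.iterations_per_extension,
                config.samples_per_chain_after_thinning,
                rng,
            )
            chain_draws.append(draws)
        per_chain = [model.constrain(d) for d in chain_draws]
        mon = np.stack(
            [np.column_stack([pc[p] for p in model.monitored]) for pc in per_chain]
        )  # (m, n, p)
        shrink = multivariate_psrf(mon)
        if shrink < config.shrink_threshold:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"{model.chem_id}: chains not converged after {n_ext} extension(s) "
            f"(shrink factor {shrink:.3f}); summaries reported anyway",
            stacklevel=2,
        )

    chain_samples = {
        p: np.stack([pc[p] for pc in per_chain]) for p in per_chain[0]
    }
    pooled = {p: v.reshape(-1) for p, v in chain_samples.items()}
    summaries = []
    for p, v in pooled.items():
        lo, med, hi = np.percentile(v, [2.5, 50.0, 97.5])
        summaries.append(
            PosteriorSummary(
                chem_id=model.chem_id,
                parameter=p,
                median=float(med),
                ci_lower=float(lo),
                ci_upper=float(hi),
                n_samples=int(v.size),
                shrink_factor=potential_scale_reduction(chain_samples[p]),
                converged=converged,
                uncertain=(
                    flag_uncertain(lo, hi) if p in model.positive_params else False
                ),
            )
        )
    return McmcResult(
        summaries=summaries,
        samples=pooled,
        chain_samples=chain_samples,
        shrink_factor=float(shrink),
        converged=converged,
        n_extensions=n_ext,
    )
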