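"""End-to-end orchestration: calibration → assay estimates → IVIVE.

For every chemical with data, the pipeline fits one calibration per batch
(measurement day), back-calculates assay-sample concentrations, censors
values below the batch eMDL, applies the plasma-stability and abiotic
screens, estimates f_up and Cl_int, and — when molecular weight and
blood:plasma information allow — carries both through IVIVE to C_ss and
AED. Chemicals that yield no usable estimate end up in the exclusion log
with a reason; every chemical with data appears in exactly one of the two
output tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import bayes as _bayes
from .calibration import (
    CalibrationModel,
    SingularFitError,
    back_calculate,
    estimate_eloq,
    estimate_emdl,
    select_calibration,
)
from .clearance import (
    DepletionFit,
    abiotic_exclusion,
    background_adjust,
    fit_depletion,
    truncate_series,
)
from .datamodel import PipelineConfig, validate_chemicals, validate_measurements
from .ivive import IVIVEParams, run_ivive
from .ppb import analyze_uc

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    """Tidy per-chemical results plus the exclusion log."""

    results: pd.DataFrame
    exclusions: pd.DataFrame
    calibrations: dict = field(default_factory=dict)
    posteriors: dict = field(default_factory=dict)


_RESULT_COLUMNS = [
    "chem_id",
    "fup",
    "fup_raw",
    "stability_ratio",
    "fup_flag",
    "clint",
    "k_met",
    "t_half",
    "f_pvalue",
    "significant",
    "background_k",
    "adjusted",
    "excluded_abiotic",
    "truncation_time",
    "clint_flag",
    "fub",
    "cl_renal",
    "cl_hep",
    "css",
    "aed",
]


def _calibrate_batches(std_rows: pd.DataFrame, chem_id: str) -> dict:
    """Fit and annotate one calibration model per batch with standards."""
    models: dict[str, CalibrationModel] = {}
    for batch, grp in std_rows.groupby("batch_id"):
        try:
            model = select_calibration(grp, chem_id=chem_id, batch_id=str(batch))
        except SingularFitError:
            continue
        usable = grp[~grp["below_detection"].astype(bool)]
        by_level = {
            float(level): sub["response_ratio"].to_numpy(float)
            for level, sub in usable.groupby("nominal_conc")
        }
        sets7 = {
            level: back_calculate(model, resp[:7], check_range=False)
            for level, resp in by_level.items()
            if resp.size >= 7
        }
        if sets7:
            model.emdl = estimate_emdl(sets7[min(sets7)])
            model.eloq = estimate_eloq(sets7)
            if np.isfinite(model.eloq) and model.eloq < model.emdl:
                model.eloq = model.emdl  # a level below detection cannot quantify
        models[str(batch)] = model
    return models


def _concentrations(
    rows: pd.DataFrame, models: dict, warn_extrapolation: bool = False
) -> np.ndarray:
    """Back-calculate concentrations, censoring below-eMDL values to NaN."""
    conc = np.full(len(rows), np.nan)
    for i, (_, row) in enumerate(rows.iterrows()):
        model = models.get(str(row["batch_id"]))
        if model is None or not model.accepted or row["below_detection"]:
            continue
        with warnings.catch_warnings():
            if not warn_extrapolation:
                warnings.simplefilter("ignore")
            c = back_calculate(model, row["response_ratio"])
        if np.isfinite(model.emdl) and c < model.emdl:
            c = np.nan
        conc[i] = c
    return conc


def _depletion_frame(rows: pd.DataFrame, models: dict) -> pd.DataFrame:
    out = rows[["time_min", "replicate", "sample_type"]].copy()
    out["conc"] = _concentrations(rows, models)
    return out


def run_pipeline(
    measurements: pd.DataFrame,
    chemicals: Optional[pd.DataFrame] = None,
    config: Optional[PipelineConfig] = None,
) -> PipelineResult:
    """Run the full analysis for every chemical in ``measurements``.

    Parameters
    ----------
    measurements, chemicals : pandas.DataFrame
        Tables in the :mod:`invitrotk.datamodel` schemas; ``chemicals`` is
        optional but required for the IVIVE stage.
    config : PipelineConfig, optional

    Returns
    -------
    PipelineResult
        ``results`` has one row per chemical with at least one usable
        estimate; ``exclusions`` one row per chemical with data but no
        usable estimate. Their row counts always sum to the number of
        chemicals with measurements.
    """
    config = config or PipelineConfig()
    measurements = validate_measurements(measurements)
    chem_meta: dict[str, pd.Series] = {}
    if chemicals is not None and len(chemicals):
        chemicals = validate_chemicals(chemicals)
        chem_meta = {str(r["chem_id"]): r for _, r in chemicals.iterrows()}

    if measurements.empty:
        warnings.warn("empty measurements table; nothing to analyse", stacklevel=2)
        return PipelineResult(
            results=pd.DataFrame(columns=_RESULT_COLUMNS),
            exclusions=pd.DataFrame(columns=["chem_id", "reason"]),
        )

    results: list[dict] = []
    exclusions: list[dict] = []
    all_models: dict = {}
    posteriors: dict = {}

    for chem_id, rows in measurements.groupby("chem_id", sort=True):
        chem_id = str(chem_id)
        std_rows = rows[rows["sample_type"] == "standard"]
        models = _calibrate_batches(std_rows, chem_id)
        all_models.update({(chem_id, b): m for b, m in models.items()})
        accepted = {b for b, m in models.items() if m.accepted}

        row: dict = {c: np.nan for c in _RESULT_COLUMNS}
        row["chem_id"] = chem_id
        reasons: list[str] = []
        have_any = False

        # ---- plasma protein binding -------------------------------------
        uc = rows[rows["assay"] == "uc_ppb"]
        if len(uc):
            uc_batches = set(uc["batch_id"].astype(str))
            if not uc_batches & accepted:
                reasons.append("no calibration for UC assay")
            else:
                conc = _concentrations(uc, models)
                stype = uc["sample_type"].to_numpy()
                res = analyze_uc(
                    chem_id,
                    conc[stype == "AF"],
                    conc[stype == "T1hr"],
                    conc[stype == "T5hr"],
                    cutoff=config.plasma_loss_cutoff,
                )
                row["stability_ratio"] = res.stability_ratio
                if res.excluded:
                    reasons.append(res.exclusion_reason)
                else:
                    row["fup"] = res.fup_point
                    row["fup_raw"] = res.fup_raw
                    row["fup_flag"] = res.exclusion_reason  # e.g. stability unknown
                    have_any = True

        # ---- hepatocyte clearance ---------------------------------------
        hep = rows[rows["assay"] == "hep_clearance"]
        if len(hep):
            hep_batches = set(hep["batch_id"].astype(str))
            if not hep_batches & accepted:
                reasons.append("no calibration for depletion assay")
            else:
                series = {
                    stype: _depletion_frame(sub, models)
                    for stype, sub in hep.groupby("sample_type")
                }
                cells = series.get("hep_cells")
                cellfree = series.get("cellfree_ctrl")
                abiotic = None
                if cellfree is not None:
                    abiotic = abiotic_exclusion(
                        cellfree,
                        cutoff=config.abiotic_loss_cutoff,
                        check_time=config.abiotic_check_time,
                    )
                row["excluded_abiotic"] = bool(abiotic) if abiotic is not None else np.nan
                if abiotic:
                    reasons.append(
                        f"abiotic instability: >= {100 * config.abiotic_loss_cutoff:.0f}% "
                        f"cell-free loss at T{config.abiotic_check_time:.0f}"
                    )
                elif cells is None or cells["conc"].notna().sum() < 2:
                    reasons.append("no quantifiable whole-cell depletion series")
                else:
                    cells_t, t_trunc = truncate_series(cells)
                    cells_fit = fit_depletion(
                        cells_t["time_min"],
                        np.log(cells_t["conc"]),
                        alpha=config.alpha_ftest,
                        chem_id=chem_id,
                        condition="cells",
                    )
                    cells_fit.truncation_time = t_trunc
                    cf_fit = None
                    if cellfree is not None:
                        cf_t = cellfree[cellfree["time_min"] <= t_trunc]
                        with np.errstate(divide="ignore", invalid="ignore"):
                            cf_fit = fit_depletion(
                                cf_t["time_min"],
                                np.log(cf_t["conc"]),
                                alpha=config.alpha_ftest,
                                chem_id=chem_id,
                                condition="cellfree",
                            )
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        adj = background_adjust(cells_fit, cf_fit)
                    row.update(
                        clint=adj.clint,
                        k_met=adj.k,
                        t_half=adj.t_half,
                        f_pvalue=adj.f_pvalue,
                        significant=adj.significant,
                        background_k=adj.background_k,
                        adjusted=adj.adjusted,
                        truncation_time=adj.truncation_time,
                        clint_flag=adj.anomaly,
                    )
                    if abiotic is None:
                        row["clint_flag"] = (
                            str(row.get("clint_flag") or "") + " abiotic stability unknown"
                        ).strip()
                    have_any = True

        # ---- optional Bayesian uncertainty ------------------------------
        if config.run_bayes and have_any:
            bc = _bayes.BayesConfig(**{"seed": config.seed, **config.bayes_options})
            chem_post = {}
            try:
                if np.isfinite(row.get("fup", np.nan)):
                    model = _bayes.UCBindingModel(
                        std_rows[std_rows["batch_id"].astype(str).isin(
                            set(uc["batch_id"].astype(str)))],
                        uc,
                        censor_limit=_censor_limit(models, uc),
                        chem_id=chem_id,
                    )
                    chem_post["uc"] = _bayes.run_mcmc(model, bc)
                if np.isfinite(row.get("clint", np.nan)) and not row.get("excluded_abiotic"):
                    model = _bayes.ClearanceModel(
                        std_rows[std_rows["batch_id"].astype(str).isin(
                            set(hep["batch_id"].astype(str)))],
                        hep,
                        censor_limit=_censor_limit(models, hep),
                        chem_id=chem_id,
                    )
                    chem_post["clearance"] = _bayes.run_mcmc(model, bc)
            except ValueError as exc:
                warnings.warn(f"{chem_id}: Bayesian stage skipped ({exc})", stacklevel=2)
            if chem_post:
                posteriors[chem_id] = chem_post

        # ---- IVIVE -------------------------------------------------------
        meta = chem_meta.get(chem_id)
        if (
            have_any
            and meta is not None
            and np.isfinite(row.get("fup", np.nan))
            and np.isfinite(row.get("clint", np.nan))
            and row["fup"] > 0
        ):
            try:
                params = IVIVEParams(**config.ivive_options)
                ires = run_ivive(
                    chem_id,
                    fup=row["fup"],
                    clint=row["clint"],
                    mol_weight=float(meta["mol_weight"]),
                    loec=None if pd.isna(meta["loec"]) else float(meta["loec"]),
                    rb=None if pd.isna(meta["rb"]) else float(meta["rb"]),
                    ionization_class=str(meta["ionization_class"]),
                    params=params,
                )
                row.update(
                    fub=ires.fub, cl_renal=ires.cl_renal, cl_hep=ires.cl_hep,
                    css=ires.css, aed=ires.aed,
                )
            except ValueError as exc:
                warnings.warn(f"{chem_id}: IVIVE skipped ({exc})", stacklevel=2)

        if have_any:
            results.append(row)
        else:
            exclusions.append(
                {"chem_id": chem_id, "reason": "; ".join(reasons) or "no usable data"}
            )

    return PipelineResult(
        results=pd.DataFrame(results, columns=_RESULT_COLUMNS),
        exclusions=pd.DataFrame(exclusions, columns=["chem_id", "reason"]),
        calibrations=all_models,
        posteriors=posteriors,
    )


def _censor_limit(models: dict, rows: pd.DataFrame) -> Optional[float]:
    """Concentration censor threshold for the Bayes stage: the largest batch
    eMDL among the batches present (None if no row is censored)."""
    if not rows["below_detection"].any():
        return None
    emdls = [
        models[b].emdl
        for b in set(rows["batch_id"].astype(str))
        if b in models and np.isfinite(models[b].emdl)
    ]
    return max(emdls) if emdls else None
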