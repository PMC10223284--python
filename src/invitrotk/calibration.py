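"""Response-ratio calibration: curve fitting, inverse prediction, eMDL/eLOQ.

Quantitation rests on per-chemical, per-batch calibration curves relating the
analyte:internal-standard response ratio to concentration (nM at instrument).
Curves are linear or quadratic, optionally weighted by 1/x or 1/x², and a
curve is *accepted* only when back-calculating every calibration standard
through it reproduces the nominal value within ±30% — the standard
bioanalytical accuracy rule.

Two detection thresholds are estimated from seven replicate injections of a
low-end standard:

* eMDL — the smallest concentration distinguishable from a blank with 99%
  confidence: ``sd(back-calculated concentrations) × t(0.99, 6 df)``. The
  t multiplier (≈3.14) is computed from the t distribution at run time.
* eLOQ — the lowest calibration level at which *all seven* replicate
  back-calculations fall within ±30% of nominal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CalibrationModel",
    "SingularFitError",
    "fit_calibration",
    "select_calibration",
    "back_calculate",
    "estimate_emdl",
    "estimate_eloq",
    "emdl_t_multiplier",
    "ACCURACY_TOLERANCE_PCT",
    "WEIGHTING_ORDER",
]

#: back-calculated accuracy must fall within nominal ± this percentage
ACCURACY_TOLERANCE_PCT = 30.0

#: weighting schemes tried, in order, when selecting a calibration model
WEIGHTING_ORDER = ("none", "1/x", "1/x2")


class SingularFitError(ValueError):
    """The standards cannot identify the curve (e.g. all responses equal)."""


@dataclass
class CalibrationModel:
    """A fitted response-ratio ↔ concentration mapping for one (chemical, batch).

    Attributes
    ----------
    coefficients : numpy.ndarray
        ``[intercept, slope]`` or ``[intercept, slope, curvature]`` in
        ratio-per-nM units.
    accuracy_table : pandas.DataFrame
        One row per calibration level with columns ``nominal_conc``,
        ``back_calculated`` (mean over replicate injections of the level)
        and ``accuracy_pct`` (back-calculated as a percentage of nominal).
    accepted : bool
        True iff every level's accuracy lies within ±30% of nominal and
        the fitted slope is positive.
    emdl, eloq : float
        Detection and quantitation limits in nM (NaN until estimated).
    """

    chem_id: str
    batch_id: str
    model_form: str
    weighting: str
    coefficients: np.ndarray
    accuracy_table: pd.DataFrame
    accepted: bool
    emdl: float = np.nan
    eloq: float = np.nan
    conc_range: tuple = (np.nan, np.nan)
    response_range: tuple = (np.nan, np.nan)

    @property
    def intercept(self) -> float:
        return float(self.coefficients[0])

    @property
    def slope(self) -> float:
        return float(self.coefficients[1])

    @property
    def curvature(self) -> float:
        return float(self.coefficients[2]) if len(self.coefficients) == 3 else 0.0

    def predict(self, conc) -> np.ndarray:
        """Forward curve: expected response ratio at concentration ``conc`` (nM)."""
        c = np.asarray(conc, dtype=float)
        return self.intercept + self.slope * c + self.curvature * c**2


def _weights(conc: np.ndarray, weighting: str) -> np.ndarray:
    if weighting == "none":
        return np.ones_like(conc)
    if weighting == "1/x":
        return 1.0 / conc
    if weighting == "1/x2":
        return 1.0 / conc**2
    raise ValueError(f"unknown weighting {weighting!r}")


def fit_calibration(
    standards: pd.DataFrame,
    model_form: str = "linear",
    weighting: str = "none",
    chem_id: Optional[str] = None,
    batch_id: Optional[str] = None,
) -> CalibrationModel:
    """Fit a weighted least-squares calibration curve to standards.

    Parameters
    ----------
    standards : pandas.DataFrame
        Rows with ``nominal_conc`` and ``response_ratio``; below-detection
        rows (NaN response) are ignored.
    model_form : {"linear", "quadratic"}
    weighting : {"none", "1/x", "1/x2"}

    Raises
    ------
    SingularFitError
        If all responses are identical or fewer than 3 distinct levels remain.
    """
    if model_form not in ("linear", "quadratic"):
        raise ValueError(f"unknown model_form {model_form!r}")
    use = standards.dropna(subset=["response_ratio"])
    conc = use["nominal_conc"].to_numpy(dtype=float)
    resp = use["response_ratio"].to_numpy(dtype=float)
    n_levels = np.unique(conc).size
    order = 2 if model_form == "quadratic" else 1
    if n_levels < order + 1 or n_levels < 3:
        raise SingularFitError(
            f"need at least 3 distinct levels (got {n_levels}) for a {model_form} fit"
        )
    if n_levels < 5:
        warnings.warn(
            f"only {n_levels} distinct calibration levels; fit is degenerate "
            "relative to the 15-point design",
            stacklevel=2,
        )
    if np.ptp(resp) == 0.0:
        raise SingularFitError("all responses identical; curve is unidentifiable")

    w = np.sqrt(_weights(conc, weighting))
    X = np.vander(conc, order + 1, increasing=True)
    beta, *_ = np.linalg.lstsq(X * w[:, None], resp * w, rcond=None)

    model = CalibrationModel(
        chem_id=chem_id if chem_id is not None else str(use["chem_id"].iloc[0]) if "chem_id" in use else "",
        batch_id=batch_id if batch_id is not None else str(use["batch_id"].iloc[0]) if "batch_id" in use else "",
        model_form=model_form,
        weighting=weighting,
        coefficients=beta,
        accuracy_table=pd.DataFrame(),
        accepted=False,
        conc_range=(float(conc.min()), float(conc.max())),
        response_range=(float(resp.min()), float(resp.max())),
    )
    back = back_calculate(model, resp, check_range=False)
    # accuracy is judged per calibration level: replicate injections of a
    # level are averaged before comparison with nominal
    per_level = (
        pd.DataFrame({"nominal_conc": conc, "back_calculated": back})
        .groupby("nominal_conc", as_index=False)
        .mean()
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        per_level["accuracy_pct"] = (
            100.0 * per_level["back_calculated"] / per_level["nominal_conc"]
        )
    model.accuracy_table = per_level
    accuracy = per_level["accuracy_pct"].to_numpy()
    within = np.isfinite(accuracy) & (np.abs(accuracy - 100.0) <= ACCURACY_TOLERANCE_PCT)
    model.accepted = bool(within.all())
    if model.slope < 0:
        warnings.warn(
            f"negative fitted slope for {model.chem_id}/{model.batch_id}; model rejected",
            stacklevel=2,
        )
        model.accepted = False
    return model


def select_calibration(
    standards: pd.DataFrame,
    chem_id: Optional[str] = None,
    batch_id: Optional[str] = None,
    forms: Sequence[str] = ("linear", "quadratic"),
) -> CalibrationModel:
    """Choose the simplest accepted calibration model.

    Tries each model form with unweighted, then 1/x, then 1/x² regression,
    returning the first whose accuracy table passes the ±30% rule. If none
    passes, the candidate with the most passing levels is returned with
    ``accepted=False``.
    """
    best = None
    best_score = -1
    for form in forms:
        for weighting in WEIGHTING_ORDER:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    cand = fit_calibration(
                        standards, form, weighting, chem_id=chem_id, batch_id=batch_id
                    )
            except SingularFitError:
                continue
            if cand.accepted:
                return cand
            acc = cand.accuracy_table["accuracy_pct"].to_numpy()
            score = int(np.sum(np.isfinite(acc) & (np.abs(acc - 100.0) <= ACCURACY_TOLERANCE_PCT)))
            if score > best_score:
                best, best_score = cand, score
    if best is None:
        raise SingularFitError("no calibration model could be fitted")
    return best


def back_calculate(
    model: CalibrationModel,
    response_ratio,
    check_range: bool = True,
    domain_factor: float = 1.2,
):
    """Invert the calibration curve: response ratio → concentration (nM).

    For a quadratic curve the root lying inside
    ``[0, domain_factor × top calibration level]`` is chosen; if no real
    root, or both roots, lie in that domain, NaN is returned (a censored /
    invalid result rather than an exception). Responses outside the
    calibrated response range are still inverted but trigger an
    extrapolation warning when ``check_range`` is true.

    Returns a float for scalar input, else an ndarray.
    """
    r = np.atleast_1d(np.asarray(response_ratio, dtype=float))
    b0, b1, b2 = model.intercept, model.slope, model.curvature
    if check_range and np.isfinite(model.response_range[0]):
        lo, hi = model.response_range
        out_of_range = (r < lo) | (r > hi)
        if np.any(out_of_range & np.isfinite(r)):
            warnings.warn(
                f"{int(np.sum(out_of_range & np.isfinite(r)))} response(s) outside the "
                "calibrated range; back-calculation is an extrapolation",
                stacklevel=2,
            )
    if b2 == 0.0:
        with np.errstate(invalid="ignore", divide="ignore"):
            conc = (r - b0) / b1
    else:
        top = model.conc_range[1] if np.isfinite(model.conc_range[1]) else np.inf
        hi = domain_factor * top
        conc = np.full_like(r, np.nan)
        disc = b1**2 - 4.0 * b2 * (b0 - r)
        ok = disc >= 0
        sq = np.sqrt(np.where(ok, disc, 0.0))
        roots = np.stack([(-b1 + sq) / (2 * b2), (-b1 - sq) / (2 * b2)])
        in_dom = ok & (roots >= 0) & (roots <= hi)
        n_in = in_dom.sum(axis=0)
        take = n_in == 1
        conc[take] = np.where(in_dom[0, take], roots[0, take], roots[1, take])
        # two admissible roots → ambiguous inversion, reported as invalid
    if np.isscalar(response_ratio) or np.ndim(response_ratio) == 0:
        return float(conc[0])
    return conc


def emdl_t_multiplier(n_replicates: int = 7, confidence: float = 0.99) -> float:
    """One-tailed t critical value with ``n_replicates − 1`` degrees of freedom."""
    return float(stats.t.ppf(confidence, n_replicates - 1))


def estimate_emdl(reported_concs, confidence: float = 0.99) -> float:
    """Estimated method detection limit from 7 replicate low-level injections.

    ``eMDL = sd(back-calculated concentrations) × t(confidence, 6 df)``.
    Exactly seven replicates are required: the degrees of freedom and the
    t value are tied to n = 7.
    """
    c = np.asarray(reported_concs, dtype=float)
    if c.size != 7:
        raise ValueError(f"eMDL requires exactly 7 replicate concentrations, got {c.size}")
    return float(np.std(c, ddof=1) * emdl_t_multiplier(7, confidence))


def estimate_eloq(levels: Mapping[float, Sequence[float]]) -> float:
    """Estimated limit of quantitation.

    Parameters
    ----------
    levels : mapping
        ``{nominal concentration: 7 back-calculated replicate concentrations}``.

    Returns
    -------
    float
        The lowest level at which all seven replicates fall within ±30% of
        nominal; NaN if no level qualifies.
    """
    for nominal in sorted(levels):
        reps = np.asarray(levels[nominal], dtype=float)
        if reps.size != 7:
            raise ValueError(f"level {nominal}: eLOQ requires 7 replicates, got {reps.size}")
        with np.errstate(invalid="ignore"):
            acc = 100.0 * reps / nominal
        if np.all(np.isfinite(acc) & (np.abs(acc - 100.0) <= ACCURACY_TOLERANCE_PCT)):
            return float(nominal)
    return float("nan")
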