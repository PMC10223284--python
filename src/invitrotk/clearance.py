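"""Hepatocyte intrinsic clearance by substrate depletion.

Suspended primary human hepatocytes (50,000 cells per 100 µL well) are
incubated with the test chemical at 1 µM and the parent compound is
quantified over a time course (design grid 0, 15, 30, 60, 120, 240 min,
triplicate wells). Depletion is analysed in semi-log form: ordinary least
squares of ln(concentration) on time, with an F-test of whether the slope
differs from zero. For a significant negative slope,

    k      = −slope                 (1/min)
    T½     = ln(2) / k              (min)
    Cl_int = 2000 × k               (µL / (min × 10⁶ cells))

where 2000 µL is the assay volume containing one million cells at the
plated density — so ``Cl_int = 2000 × k`` holds as an exact identity.

Parallel negative controls (cell-free medium and metabolically inactivated
hepatocytes) isolate abiotic loss. Chemicals losing 50% or more in the
cell-free control by 120 min are excluded as unstable; otherwise the
cell-free rate constant is subtracted from the whole-cell rate
(``k_met = max(0, k_cells − k_cellfree)``) over time ranges truncated to the
last timepoint at which the cells condition remains quantifiable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DepletionFit",
    "volume_per_million_cells",
    "CLINT_VOLUME_SCALAR_UL",
    "fit_depletion",
    "truncate_series",
    "background_adjust",
    "abiotic_exclusion",
    "REFERENCE_COMPOUND",
]

#: QC chemical run concurrently to confirm hepatocyte metabolic competence
REFERENCE_COMPOUND = "ametryn"


def volume_per_million_cells(
    cells_per_well: float = 50_000, well_volume_ul: float = 100.0
) -> float:
    """Assay volume (µL) containing 10⁶ cells at the plated density."""
    return 1e6 / cells_per_well * well_volume_ul


#: µL containing one million hepatocytes at 50,000 cells / 100 µL
CLINT_VOLUME_SCALAR_UL = volume_per_million_cells()


@dataclass
class DepletionFit:
    """Result of a semi-log depletion regression for one condition.

    ``clint = scalar × k`` is an exact algebraic identity whenever a fit is
    reported; ``clint = 0`` encodes "no detectable clearance".
    """

    chem_id: str
    condition: str
    slope: float = np.nan          # 1/min
    k: float = 0.0                 # −slope when significant, else 0
    t_half: float = np.inf         # min
    clint: float = 0.0             # µL/(min × 10⁶ cells)
    f_pvalue: float = np.nan
    significant: bool = False
    anomaly: str = ""
    n_points: int = 0
    truncation_time: float = np.nan
    background_k: float = np.nan
    adjusted: bool = False
    excluded_abiotic: bool = False


def fit_depletion(
    times,
    ln_conc,
    alpha: float = 0.05,
    chem_id: str = "",
    condition: str = "cells",
    scalar: float = CLINT_VOLUME_SCALAR_UL,
) -> DepletionFit:
    """Regress ln(concentration) on time and derive k, T½ and Cl_int.

    All replicate points enter the regression (maximising F-test degrees of
    freedom). The slope is declared significant iff the two-sided F-test
    p-value is below ``alpha`` *and* the slope is negative; a significantly
    positive slope is flagged as an anomaly and treated as no clearance.
    Censored points should be passed as NaN; they are dropped.

    Notes
    -----
    For a single regressor the standard F-test of "slope = 0" is identical
    to the two-sided t-test reported by :func:`scipy.stats.linregress`.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(ln_conc, dtype=float)
    ok = np.isfinite(t) & np.isfinite(y)
    t, y = t[ok], y[ok]
    fit = DepletionFit(chem_id=chem_id, condition=condition, n_points=int(t.size))
    if np.unique(t).size < 2:
        fit.anomaly = "unfit: fewer than 2 distinct quantifiable timepoints"
        return fit
    fit.truncation_time = float(t.max())
    res = stats.linregress(t, y)
    fit.slope = float(res.slope)
    fit.f_pvalue = float(res.pvalue)
    if fit.f_pvalue < alpha and fit.slope < 0:
        fit.significant = True
        fit.k = -fit.slope
        fit.t_half = float(np.log(2) / fit.k)
        fit.clint = scalar * fit.k
    elif fit.f_pvalue < alpha and fit.slope > 0:
        fit.anomaly = "significant positive slope (apparent concentration increase)"
        warnings.warn(
            f"{chem_id}/{condition}: {fit.anomaly}; Cl_int reported as 0", stacklevel=2
        )
    return fit


def truncate_series(
    series: pd.DataFrame, min_quantifiable: int = 2
) -> tuple[pd.DataFrame, float]:
    """Truncate a depletion series where the compound falls below quantitation.

    Keeps timepoints up to (and including) the last one with at least
    ``min_quantifiable`` non-censored replicates, implementing matched
    analysis windows for chemicals cleared before the end of the time
    course. ``series`` needs columns ``time_min`` and ``conc`` (NaN =
    censored).

    Returns the truncated frame and the truncation time (NaN if no
    timepoint qualifies).
    """
    counts = series.dropna(subset=["conc"]).groupby("time_min").size()
    good = counts[counts >= min_quantifiable]
    if good.empty:
        return series.iloc[0:0], float("nan")
    t_max = float(good.index.max())
    return series[series["time_min"] <= t_max], t_max


def background_adjust(
    cells_fit: DepletionFit,
    cellfree_fit: Optional[DepletionFit],
    scalar: float = CLINT_VOLUME_SCALAR_UL,
) -> DepletionFit:
    """Subtract the abiotic (cell-free) rate constant from the whole-cell rate.

    ``k_met = max(0, k_cells − k_cellfree)``; subtraction acts on rate
    constants because both compartments follow first-order loss. The result
    is ``adjusted=True`` only when the cell-free slope itself was
    significant (otherwise its k is 0 and adjustment is a no-op). A missing
    cell-free fit leaves the whole-cell rate unadjusted with a warning.

    Both fits should be computed over series truncated to the same final
    timepoint (see :func:`truncate_series`).
    """
    if cellfree_fit is None:
        if cells_fit.significant:
            warnings.warn(
                f"{cells_fit.chem_id}: no cell-free control; Cl_int reported unadjusted",
                stacklevel=2,
            )
        return replace(cells_fit, anomaly=(cells_fit.anomaly + " unadjusted:no cell-free control").strip())
    k_bg = cellfree_fit.k if cellfree_fit.significant else 0.0
    k_met = max(0.0, cells_fit.k - k_bg)
    out = replace(
        cells_fit,
        k=k_met,
        t_half=float(np.log(2) / k_met) if k_met > 0 else np.inf,
        clint=scalar * k_met,
        background_k=k_bg,
        adjusted=bool(cellfree_fit.significant),
    )
    return out


def abiotic_exclusion(
    cellfree_series: pd.DataFrame,
    cutoff: float = 0.50,
    check_time: float = 120.0,
    time_tol: float = 1e-9,
) -> Optional[bool]:
    """Screen the cell-free control for abiotic instability.

    Excluded iff the mean cell-free concentration at ``check_time`` has
    fallen to ``(1 − cutoff)`` of the mean at t = 0 *or lower* (the boundary
    is inclusive: exactly 50% loss excludes). ``cellfree_series`` needs
    columns ``time_min`` and ``conc``; censored (NaN) concentrations count
    as zero here because falling below detection is itself loss.

    Returns True/False, or None when either timepoint is missing (cannot
    assess — caller should flag).
    """
    s = cellfree_series.copy()
    s["conc"] = s["conc"].fillna(0.0)
    at0 = s.loc[np.isclose(s["time_min"], 0.0, atol=time_tol), "conc"]
    atT = s.loc[np.isclose(s["time_min"], check_time, atol=time_tol), "conc"]
    if at0.empty or atT.empty or at0.mean() <= 0:
        return None
    return bool(atT.mean() <= (1.0 - cutoff) * at0.mean())
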