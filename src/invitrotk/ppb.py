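"""Plasma protein binding from the ultracentrifugation (UC) assay.

Chemicals are incubated in pooled human plasma at a 10 µM assay
concentration. After 1 h an aliquot is taken (T1hr); after 5 h a second
aliquot (T5hr) and, from the ultracentrifuged remainder, the protein-free
aqueous fraction (AF). Fraction unbound in plasma is

    f_up = mean(AF concentration) / mean(T5hr concentration)

with the replicate means taken before the ratio because AF and T5hr
aliquots are unpaired. Measurement noise can push the raw ratio above 1;
the point estimate is capped at 1 (the physical maximum) while the raw
ratio is retained for transparency.

Chemical stability over the assay is screened with the T5hr/T1hr
concentration ratio: chemicals losing strictly more than 60% over the
time course are excluded from further toxicokinetic use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "UCAssayResult",
    "estimate_fup",
    "plasma_stability_screen",
    "analyze_uc",
    "summarize_fup",
    "check_reference_compound",
    "REFERENCE_COMPOUND",
]

#: QC chemical carried in every UC batch to track assay performance
REFERENCE_COMPOUND = "4NT"


@dataclass
class UCAssayResult:
    """Fraction-unbound estimate with its stability screen outcome."""

    chem_id: str
    fup_point: float = np.nan        # capped at 1
    fup_raw: float = np.nan          # uncapped AF/T5hr ratio
    stability_ratio: float = np.nan  # mean(T5hr)/mean(T1hr)
    excluded: bool = False
    exclusion_reason: str = ""
    af_concs: list = field(default_factory=list)
    t5_concs: list = field(default_factory=list)


def _clean(values) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    return v[np.isfinite(v)]


def estimate_fup(af_concs, t5_concs) -> tuple[float, float]:
    """Point estimate of fraction unbound in plasma.

    Parameters
    ----------
    af_concs, t5_concs : array-like
        Back-calculated aqueous-fraction and T5hr concentrations (nM);
        censored values should be NaN and are ignored.

    Returns
    -------
    (fup, raw_ratio) : tuple of float
        ``raw_ratio = mean(AF)/mean(T5hr)``; ``fup = min(1, raw_ratio)``.
        Both NaN when no valid pair exists or mean(T5hr) ≤ 0.
    """
    af = _clean(af_concs)
    t5 = _clean(t5_concs)
    if af.size == 0 or t5.size == 0 or np.mean(t5) <= 0:
        return float("nan"), float("nan")
    raw = float(np.mean(af) / np.mean(t5))
    return min(1.0, max(0.0, raw)), raw


def plasma_stability_screen(
    t1_concs, t5_concs, cutoff: float = 0.60
) -> tuple[float, bool]:
    """Percent-remaining screen over the UC assay time course.

    ``ratio = mean(T5hr)/mean(T1hr)``; the chemical is excluded iff the loss
    ``1 − ratio`` strictly exceeds ``cutoff`` (default 60%). A missing T1hr
    yields ``(nan, False)`` — stability unknown rather than assumed — and the
    caller should flag it.
    """
    t1 = _clean(t1_concs)
    t5 = _clean(t5_concs)
    if t1.size == 0 or np.mean(t1) <= 0:
        return float("nan"), False
    ratio = float(np.mean(t5) / np.mean(t1)) if t5.size else 0.0
    return ratio, bool((1.0 - ratio) > cutoff)


def analyze_uc(
    chem_id: str,
    af_concs,
    t1_concs,
    t5_concs,
    cutoff: float = 0.60,
) -> UCAssayResult:
    """Full UC analysis for one chemical: stability screen then f_up."""
    result = UCAssayResult(
        chem_id=chem_id,
        af_concs=list(np.atleast_1d(np.asarray(af_concs, dtype=float))),
        t5_concs=list(np.atleast_1d(np.asarray(t5_concs, dtype=float))),
    )
    ratio, excluded = plasma_stability_screen(t1_concs, t5_concs, cutoff)
    result.stability_ratio = ratio
    if excluded:
        result.excluded = True
        result.exclusion_reason = (
            f"plasma instability: {100 * (1 - ratio):.0f}% loss over assay (> {100 * cutoff:.0f}%)"
        )
        return result
    if not np.isfinite(ratio):
        result.exclusion_reason = "stability unknown (no T1hr data)"
    fup, raw = estimate_fup(af_concs, t5_concs)
    result.fup_point, result.fup_raw = fup, raw
    if not np.isfinite(fup):
        result.excluded = True
        result.exclusion_reason = "insufficient data: no quantifiable AF/T5hr pair"
    return result


def summarize_fup(values) -> dict:
    """Distribution summary of capped f_up values.

    Percentiles use linear interpolation. Returns an empty dict for empty
    input.
    """
    v = _clean(values)
    if v.size == 0:
        return {}
    return {
        "n": int(v.size),
        "min": float(v.min()),
        "p25": float(np.percentile(v, 25)),
        "median": float(np.median(v)),
        "mean": float(v.mean()),
        "max": float(v.max()),
    }


def check_reference_compound(
    fup_by_batch: dict,
    band: tuple[float, float],
    chem_id: str = REFERENCE_COMPOUND,
) -> list[str]:
    """Compare the per-batch QC-compound f_up against a historical band.

    Returns a list of warning strings (one per out-of-band batch); each is
    also emitted via :mod:`warnings`.
    """
    lo, hi = band
    out = []
    for batch, fup in sorted(fup_by_batch.items()):
        if not np.isfinite(fup) or not (lo <= fup <= hi):
            msg = (
                f"batch {batch}: reference compound {chem_id} f_up={fup!r} outside "
                f"historical band [{lo}, {hi}]"
            )
            warnings.warn(msg, stacklevel=2)
            out.append(msg)
    return out
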