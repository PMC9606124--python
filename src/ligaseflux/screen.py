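"""High-throughput screen analytics for the plate-reader (NanoLuc)
reporter assay.

Wells are normalized per plate to percent activity

    PA = 100 × (lum − med_neutral) / (med_neutral − med_negative)

so a well at the neutral-control median (cells + DMSO) reads 0% and a
well at the negative-control median (media only) reads −100%.  Raised
luminescence (reporter accumulating, PA > 0) indicates ligase
*inhibition*; lowered luminescence (PA < 0) indicates *activation* —
the convention fixed by the assay's controls (MLN-4924 up, CHX down).
Hits are wells beyond ±50% (strict inequality); hits are confirmed by
11-point 1:3 titrations fit with a four-parameter logistic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .types import DoseResponseFit

__all__ = [
    "normalize_plate",
    "call_hits",
    "four_pl",
    "titration_doses",
    "fit_dose_response",
    "selectivity_filter",
]


def normalize_plate(plate: pd.DataFrame) -> pd.DataFrame:
    """Percent activity for every compound well of one plate.

    Expects columns ``role`` ∈ {compound, neutral, negative} and ``lum``;
    medians are computed within the plate.
    """
    neutral = plate.loc[plate["role"] == "neutral", "lum"]
    negative = plate.loc[plate["role"] == "negative", "lum"]
    if neutral.empty or negative.empty:
        raise ValueError("plate needs neutral and negative control wells")
    med_neutral = float(neutral.median())
    med_negative = float(negative.median())
    if med_neutral == med_negative:
        raise ValueError("degenerate controls: median neutral equals median negative")
    comp = plate[plate["role"] == "compound"].copy()
    comp["PA"] = 100.0 * (comp["lum"] - med_neutral) / (med_neutral - med_negative)
    keep = [c for c in ("plate_id", "row", "col", "compound_id", "conc_uM", "lum", "PA") if c in comp.columns]
    return comp[keep].reset_index(drop=True)


def call_hits(pa_table: pd.DataFrame, threshold_pct: float = 50.0) -> dict[str, pd.DataFrame]:
    """Strict-threshold hit calling: PA > +threshold → inhibitor hit
    (reporter accumulates), PA < −threshold → activator hit."""
    if pa_table.empty:
        raise ValueError("empty percent-activity table")
    return {
        "inhibitor_hits": pa_table[pa_table["PA"] > threshold_pct].reset_index(drop=True),
        "activator_hits": pa_table[pa_table["PA"] < -threshold_pct].reset_index(drop=True),
    }


def four_pl(dose: np.ndarray, bottom: float, top: float, ic50: float, hill: float) -> np.ndarray:
    """response = bottom + (top − bottom) / (1 + (dose/ic50)^hill)

    ic50 is floored at a tiny positive value so optimizer excursions to
    non-positive ic50 yield finite (poor) residuals instead of NaN."""
    dose = np.asarray(dose, dtype=float)
    ratio = dose / max(ic50, 1e-12)
    return bottom + (top - bottom) / (1.0 + ratio**hill)


def titration_doses(top_uM: float = 13.0, n_points: int = 11, dilution: float = 3.0) -> np.ndarray:
    """Standard confirmation titration: ``n_points`` doses descending
    from ``top_uM`` at 1:``dilution``."""
    return top_uM / dilution ** np.arange(n_points)


def fit_dose_response(
    doses: np.ndarray,
    responses: np.ndarray,
    compound_id: str = "",
    flat_range_tol: float = 1e-6,
) -> DoseResponseFit:
    """Four-parameter logistic fit with grid-seeded initialization.

    Starts are seeded over a log-spaced IC50 grid spanning the dose range
    and Hill slopes {0.5, 1, 2, 4} (both signs of the span); the best
    start by residual norm is refined by Levenberg–Marquardt.  Fits with
    IC50 outside [min dose/10, max dose×10] are classed incomplete-curve;
    non-convergence is reported, never silently defaulted.
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if len(np.unique(doses)) < 5:
        raise ValueError("need at least 5 distinct doses")
    if not (np.all(np.isfinite(doses)) and np.all(np.isfinite(responses))):
        raise ValueError("doses and responses must be finite")

    span = float(responses.max() - responses.min())
    scale = max(abs(responses).max(), 1.0)
    if span <= max(flat_range_tol, 1e-12 * scale) or np.ptp(responses) / scale < 1e-3:
        return DoseResponseFit(
            compound_id, doses, responses,
            bottom=float(responses.mean()), top=float(responses.mean()),
            ic50_uM=np.nan, hill=np.nan, converged=False,
            residual_norm=float(np.sqrt(np.mean((responses - responses.mean()) ** 2))),
            curve_class="flat",
        )

    ic50_grid = np.geomspace(doses.min(), doses.max(), 7)
    best = None
    for ic50_0 in ic50_grid:
        for hill_0 in (0.5, 1.0, 2.0, 4.0):
            for b0, t0 in ((responses.min(), responses.max()), (responses.max(), responses.min())):
                pred = four_pl(doses, b0, t0, ic50_0, hill_0)
                ssr = float(np.sum((pred - responses) ** 2))
                if best is None or ssr < best[0]:
                    best = (ssr, (b0, t0, ic50_0, hill_0))
    p0 = best[1]
    try:
        popt, _ = curve_fit(four_pl, doses, responses, p0=p0, maxfev=20000)
    except RuntimeError:
        return DoseResponseFit(
            compound_id, doses, responses,
            bottom=np.nan, top=np.nan, ic50_uM=np.nan, hill=np.nan,
            converged=False, residual_norm=np.inf, curve_class="non_converged",
        )
    bottom, top, ic50, hill = (float(v) for v in popt)
    # canonical orientation: positive Hill slope
    if hill < 0:
        bottom, top, hill = top, bottom, -hill
    fitted = four_pl(doses, bottom, top, ic50, hill)
    resid = float(np.sqrt(np.mean((fitted - responses) ** 2)))
    in_range = doses.min() / 10.0 <= ic50 <= doses.max() * 10.0
    return DoseResponseFit(
        compound_id, doses, responses, bottom, top, float(ic50), hill,
        converged=bool(in_range and np.isfinite(ic50) and ic50 > 0),
        residual_norm=resid,
        curve_class="converged" if in_range else "incomplete_curve",
        fitted=fitted,
    )


def selectivity_filter(
    pa_target: float,
    pa_mutant: float | None,
    pa_counter: float | None,
    margin_pct: float = 20.0,
    threshold_pct: float = 50.0,
) -> dict:
    """Counter-screen selectivity: the compound must move the ligase
    reporter beyond the hit threshold while leaving the degron-mutant
    reporter and the related-ligase (Skp2) reporter inside ``margin_pct``
    (strict comparisons).  Pan-degradation actives (e.g. translation
    block) fail the mutant arm."""
    if pa_mutant is None or pa_counter is None or not np.isfinite([pa_mutant, pa_counter]).all():
        return {"selective": False, "incomplete_data": True}
    selective = (
        abs(pa_target) > threshold_pct
        and abs(pa_mutant) < margin_pct
        and abs(pa_counter) < margin_pct
    )
    return {"selective": bool(selective), "incomplete_data": False}
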