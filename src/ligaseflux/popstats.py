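"""Population-level statistics: live-to-fixed cell matching,
activity-vs-protein correlation, activity fold differences between
populations, and dose-response IC50 fold shifts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

from .screen import four_pl, fit_dose_response
from .types import DoseResponseFit

__all__ = [
    "match_live_to_fixed",
    "CorrelationResult",
    "correlate_activity_protein",
    "compare_activity_populations",
    "ic50_fold_shift",
]


def match_live_to_fixed(
    live_centroids: np.ndarray,
    fixed_centroids: np.ndarray,
    cap: float = 5.0,
) -> pd.DataFrame:
    """Globally greedy one-to-one nearest-pair matching under a distance
    cap.

    All candidate pairs within ``cap`` are sorted by distance and claimed
    greedily; no fixed cell is assigned twice.  Returns a table with
    live_index, fixed_index, match_distance (unmatched live cells get
    fixed_index = -1 and NaN distance).
    """
    live = np.atleast_2d(np.asarray(live_centroids, dtype=float))
    fixed = np.atleast_2d(np.asarray(fixed_centroids, dtype=float))
    if live.size == 0:
        raise ValueError("empty live centroid set")
    rows = []
    if fixed.size == 0:
        for i in range(len(live)):
            rows.append({"live_index": i, "fixed_index": -1, "match_distance": np.nan})
        return pd.DataFrame(rows)
    d = cdist(live, fixed)
    ii, jj = np.nonzero(d <= cap)
    order = np.argsort(d[ii, jj], kind="stable")
    used_live: set[int] = set()
    used_fixed: set[int] = set()
    assigned: dict[int, tuple[int, float]] = {}
    for idx in order:
        i, j = int(ii[idx]), int(jj[idx])
        if i in used_live or j in used_fixed:
            continue
        used_live.add(i)
        used_fixed.add(j)
        assigned[i] = (j, float(d[i, j]))
    for i in range(len(live)):
        j, dist = assigned.get(i, (-1, np.nan))
        rows.append({"live_index": i, "fixed_index": j, "match_distance": dist})
    return pd.DataFrame(rows)


@dataclass
class CorrelationResult:
    rho: float
    n: int
    method: str
    ci95: tuple[float, float]


def correlate_activity_protein(
    activity: np.ndarray,
    protein: np.ndarray,
    method: str = "spearman",
    n_boot: int = 2000,
    seed: int = 0,
) -> CorrelationResult:
    """Correlation of per-cell activity and protein level with a seeded
    bootstrap percentile 95% CI.

    Spearman is the default: immunofluorescence intensity is an unknown
    monotone transform of abundance, and rank correlation is invariant to
    it.  Pearson is available via ``method``.
    """
    a = np.asarray(activity, dtype=float)
    p = np.asarray(protein, dtype=float)
    if len(a) != len(p) or len(a) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.std(a) == 0 or np.std(p) == 0:
        raise ValueError("zero-variance input: correlation undefined")
    corr = _corr_fn(method)
    rho = float(corr(a, p))
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    n = len(a)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        ab, pb = a[idx], p[idx]
        if np.std(ab) == 0 or np.std(pb) == 0:
            boots[b] = np.nan
            continue
        boots[b] = corr(ab, pb)
    lo, hi = np.nanpercentile(boots, [2.5, 97.5])
    ci = (min(float(lo), rho), max(float(hi), rho))
    return CorrelationResult(rho=rho, n=n, method=method, ci95=ci)


def _corr_fn(method: str):
    if method == "spearman":
        return lambda a, b: stats.spearmanr(a, b).statistic
    if method == "pearson":
        return lambda a, b: stats.pearsonr(a, b).statistic
    raise ValueError(f"unknown correlation method {method!r}")


def compare_activity_populations(
    group_a: np.ndarray,
    group_b: np.ndarray,
    n_boot: int = 2000,
    seed: int = 0,
) -> dict:
    """Fold difference of medians (a / b) with a seeded bootstrap CI."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("both groups need >= 3 cells")
    med_a, med_b = float(np.median(a)), float(np.median(b))
    if med_b <= 0:
        raise ValueError("median of group_b must be positive for a fold ratio")
    rng = np.random.default_rng(seed)
    folds = np.empty(n_boot)
    for i in range(n_boot):
        mb = np.median(b[rng.integers(0, len(b), len(b))])
        ma = np.median(a[rng.integers(0, len(a), len(a))])
        folds[i] = ma / mb if mb > 0 else np.nan
    lo, hi = np.nanpercentile(folds, [2.5, 97.5])
    return {
        "median_a": med_a,
        "median_b": med_b,
        "fold": med_a / med_b,
        "ci95": (float(lo), float(hi)),
        "n_a": len(a),
        "n_b": len(b),
    }


def ic50_fold_shift(
    fit_a: DoseResponseFit,
    fit_b: DoseResponseFit,
    n_boot: int = 500,
    seed: int = 0,
) -> dict:
    """IC50 ratio (a / b) with a CI from residual resampling.

    Each bootstrap replicate adds resampled fit residuals to each fitted
    curve, refits, and records the IC50 ratio.  Refuses non-converged
    inputs."""
    for name, fit in (("a", fit_a), ("b", fit_b)):
        if not fit.converged:
            raise ValueError(f"fit {name} did not converge ({fit.curve_class}); cannot form a fold")
    fold = fit_a.ic50_uM / fit_b.ic50_uM
    rng = np.random.default_rng(seed)
    folds = []
    for _ in range(n_boot):
        pair = []
        for fit in (fit_a, fit_b):
            fitted = fit.fitted if fit.fitted is not None else four_pl(
                fit.doses, fit.bottom, fit.top, fit.ic50_uM, fit.hill
            )
            resid = fit.responses - fitted
            new = fitted + rng.choice(resid, size=len(resid), replace=True)
            refit = fit_dose_response(fit.doses, new, fit.compound_id)
            pair.append(refit.ic50_uM if refit.converged else np.nan)
        folds.append(pair[0] / pair[1] if np.isfinite(pair).all() else np.nan)
    folds = np.asarray(folds)
    if folds.size == 0 or not np.isfinite(folds).any():
        lo = hi = np.nan
    else:
        lo, hi = np.nanpercentile(folds, [2.5, 97.5])
    return {
        "fold": float(fold),
        "ci95": (float(lo), float(hi)),
        "ic50_a": fit_a.ic50_uM,
        "ic50_b": fit_b.ic50_uM,
        "n_boot_converged": int(np.isfinite(folds).sum()),
    }
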