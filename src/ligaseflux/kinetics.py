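"""Kinetic inference from reporter traces.

The central quantity is the degradation flux

    A(t) = s − dR/dt        (a.u./h)

where s is the reporter synthesis rate and dR/dt the time derivative of
the measured reporter level.  Under the balance model dR/dt = s − k·R,
the flux equals k·R: it is the instantaneous rate at which the ligase
destroys reporter, i.e. the relative ligase activity.  The synthesis
rate is read out experimentally from the post-MLN-4924 accumulation
slope (degradation fully inhibited, so dR/dt = s); half-lives come from
cycloheximide-chase decays (synthesis stopped, so R decays exponentially
at rate k).

Mitosis produces a transient apparent intensity spike (cell rounding and
nuclear envelope breakdown), which is an artifact of measurement, not
biochemistry; frames around mitosis are masked before differentiation.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

from .types import ActivityTrace, AlignedTraceSet, HalfLifeFit, ReporterTrace

__all__ = [
    "annotate_phases",
    "mask_mitotic_frames",
    "estimate_synthesis_rate",
    "compute_activity",
    "estimate_half_life",
    "align_to_mitosis",
]


# --------------------------------------------------------------------------
# phase annotation
# --------------------------------------------------------------------------

def annotate_phases(
    trace: ReporterTrace,
    geminin_trace: ReporterTrace,
    onset_fraction: float = 0.2,
    persistence_frames: int = 3,
) -> np.ndarray:
    """Label frames M / G1 / SG2 from the Geminin (APC/C-degron) channel.

    Geminin is degraded by APC/C through G1 and accumulates from S phase;
    S entry is called at the first frame where the Geminin signal exceeds
    ``baseline + onset_fraction × (max − baseline)`` and keeps rising for
    at least ``persistence_frames`` frames.  G1 runs from each mitosis to
    the onset; SG2 from onset to the next mitosis.  Traces that end
    before any onset stay G1 throughout (flagged by the absence of SG2).
    """
    if len(trace.times) != len(geminin_trace.times) or not np.allclose(
        trace.times, geminin_trace.times
    ):
        raise ValueError("trace and Geminin trace must share the time grid")
    n = trace.n_frames
    g = np.asarray(geminin_trace.R, dtype=float)
    labels = np.empty(n, dtype=object)
    labels[:] = "G1"

    anchors = [0] + [m for m in trace.mitosis_frames if 0 < m < n]
    bounds = anchors + [n]
    for start, end in zip(bounds[:-1], bounds[1:]):
        seg = g[start:end]
        if len(seg) < persistence_frames + 1:
            continue
        baseline = float(seg.min())
        rng_ = float(seg.max()) - baseline
        if rng_ <= 0:
            continue
        thresh = baseline + onset_fraction * rng_
        onset = None
        for i in range(len(seg) - persistence_frames):
            if seg[i] > thresh and np.all(np.diff(seg[i : i + persistence_frames + 1]) > 0):
                onset = i
                break
        if onset is not None:
            labels[start + onset : end] = "SG2"
    for m in trace.mitosis_frames:
        if 0 <= m < n:
            labels[m] = "M"
    return labels


def mask_mitotic_frames(trace: ReporterTrace, margin_frames: int = 2) -> ReporterTrace:
    """Return a copy with mitosis frames ± margin flagged as masked."""
    masked: set[int] = set(
        np.asarray(trace.masked_frames, dtype=int).tolist()
    ) if trace.masked_frames is not None else set()
    for m in trace.mitosis_frames:
        for f in range(m - margin_frames, m + margin_frames + 1):
            if 0 <= f < trace.n_frames:
                masked.add(f)
    out = ReporterTrace(
        cell_id=trace.cell_id,
        times=trace.times,
        R=trace.R,
        phase=trace.phase,
        mitosis_frames=list(trace.mitosis_frames),
        perturbations=list(trace.perturbations),
        lineage_parent=trace.lineage_parent,
        latent=trace.latent,
        masked_frames=np.asarray(sorted(masked), dtype=int) if masked else None,
    )
    return out


# --------------------------------------------------------------------------
# synthesis rate
# --------------------------------------------------------------------------

def _find_perturbation(trace: ReporterTrace, drug: str):
    for p in trace.perturbations:
        if p.drug == drug:
            return p
    return None


def estimate_synthesis_rate(
    traces: list[ReporterTrace],
    window_h: tuple[float, float] | None = None,
    drug: str = "MLN4924",
    residual_ratio_threshold: float = 0.9,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Population synthesis rate from post-MLN-4924 accumulation slopes.

    For each cell, a least-squares line is fit to R(t) over ``window_h``
    (hours relative to the drug's effective onset; default: onset to end
    of trace).  Returns ``(s_median, slopes, residual_decay_flags)``.
    A cell is flagged when its late-half slope falls below
    ``residual_ratio_threshold`` × its early-half slope, indicating
    incomplete degradation block (slope then underestimates s).
    """
    slopes = np.empty(len(traces))
    flags = np.zeros(len(traces), dtype=bool)
    for i, tr in enumerate(traces):
        p = _find_perturbation(tr, drug)
        if p is None:
            raise ValueError(f"trace {tr.cell_id} lacks a {drug} event")
        t0 = p.t_effective
        if window_h is None:
            lo, hi = t0, float(tr.times[-1])
        else:
            lo, hi = t0 + window_h[0], t0 + window_h[1]
        sel = (tr.times >= lo - 1e-9) & (tr.times <= hi + 1e-9) & ~tr.mask_array()
        if sel.sum() < 3:
            raise ValueError(f"trace {tr.cell_id}: fit window shorter than 3 frames")
        t = tr.times[sel]
        r = tr.R[sel]
        slopes[i] = np.polyfit(t, r, 1)[0]
        half = len(t) // 2
        if half >= 3:
            early = np.polyfit(t[:half], r[:half], 1)[0]
            late = np.polyfit(t[half:], r[half:], 1)[0]
            if early > 0 and late < residual_ratio_threshold * early:
                flags[i] = True
    return float(np.median(slopes)), slopes, flags


# --------------------------------------------------------------------------
# activity
# --------------------------------------------------------------------------

def compute_activity(
    trace: ReporterTrace,
    s: float,
    smoothing_frames: int = 5,
    level_floor: float = 1e-6,
) -> ActivityTrace:
    """Degradation flux A = s − dR/dt via a centered local linear fit.

    The derivative at each frame is the slope of a least-squares line
    over a centered window of ``smoothing_frames`` frames, using only
    unmasked frames; frames whose window holds fewer than 3 valid points
    (or that are themselves masked) propagate as NaN.
    """
    if s < 0:
        raise ValueError("synthesis rate must be >= 0")
    if smoothing_frames < 3 or smoothing_frames % 2 == 0:
        raise ValueError("smoothing_frames must be an odd number >= 3")
    mask = trace.mask_array()
    n = trace.n_frames
    if mask.all():
        raise ValueError("all frames masked; no activity can be computed")
    half = smoothing_frames // 2
    deriv = np.full(n, np.nan)
    t = trace.times
    r = np.asarray(trace.R, dtype=float)
    valid = ~mask & np.isfinite(r)
    for i in range(n):
        if not valid[i]:
            continue
        lo, hi = max(0, i - half), min(n, i + half + 1)
        sel = valid[lo:hi]
        if sel.sum() < 3:
            continue
        tw = t[lo:hi][sel]
        rw = r[lo:hi][sel]
        deriv[i] = np.polyfit(tw, rw, 1)[0]
    a = s - deriv
    k_specific = np.where(
        np.isfinite(a) & (r > level_floor), a / np.maximum(r, level_floor), np.nan
    )
    return ActivityTrace(
        cell_id=trace.cell_id,
        times=t,
        A=a,
        s_used=s,
        k_specific=k_specific,
        masked_frames=trace.masked_frames,
        mitosis_frames=list(trace.mitosis_frames),
    )


# --------------------------------------------------------------------------
# half-life
# --------------------------------------------------------------------------

def estimate_half_life(
    trace: ReporterTrace,
    window_h: tuple[float, float] | None = None,
    drug: str = "CHX",
    level_floor: float = 1e-9,
    max_nonpositive_fraction: float = 0.1,
) -> HalfLifeFit:
    """Cycloheximide-chase half-life by log-linear regression.

    With synthesis stopped, R(t) = R(t0)·exp(−k (t−t0)); ln R is fit
    against t by least squares over ``window_h`` relative to the drug's
    effective onset (default: onset to trace end).  Log-linear fitting is
    variance-stabilizing under multiplicative measurement noise.  A
    non-positive fitted k is reported as no-decay with infinite t½.
    """
    p = _find_perturbation(trace, drug)
    if p is None:
        raise ValueError(f"trace {trace.cell_id} lacks a {drug} event")
    t0 = p.t_effective
    if window_h is None:
        lo, hi = t0, float(trace.times[-1])
    else:
        lo, hi = t0 + window_h[0], t0 + window_h[1]
    sel = (trace.times >= lo - 1e-9) & (trace.times <= hi + 1e-9) & ~trace.mask_array()
    r = np.asarray(trace.R, dtype=float)[sel]
    t = trace.times[sel]
    nonpos = r <= level_floor
    if nonpos.mean() > max_nonpositive_fraction:
        raise ValueError("too many non-positive intensities for a log-linear fit")
    t, r = t[~nonpos], r[~nonpos]
    if len(t) < 5:
        raise ValueError("fewer than 5 usable frames in the fit window")
    res = stats.linregress(t, np.log(r))
    k_fit = -float(res.slope)
    r2 = float(res.rvalue**2)
    if k_fit <= 0:
        return HalfLifeFit(
            t_half=math.inf, k_fit=k_fit, fit_window=(lo, hi),
            r_squared=r2, n_frames=len(t), no_decay=True,
        )
    return HalfLifeFit(
        t_half=math.log(2) / k_fit, k_fit=k_fit, fit_window=(lo, hi),
        r_squared=r2, n_frames=len(t),
    )


# --------------------------------------------------------------------------
# mitosis alignment
# --------------------------------------------------------------------------

def align_to_mitosis(
    traces: list[ReporterTrace] | list[ActivityTrace],
    values: list[np.ndarray] | None = None,
    anchor: int = 0,
    window_h: tuple[float, float] = (-10.0, 10.0),
    min_count: int = 3,
) -> AlignedTraceSet:
    """Re-index traces so the anchor mitosis of each sits at relative
    time 0; traces without a mitosis are excluded.

    ``values`` overrides the per-trace value array (e.g. activity instead
    of intensity); ``anchor`` selects which mitosis (0 = first, -1 =
    last).  The per-timepoint median is reported only where at least
    ``min_count`` traces contribute.
    """
    usable = [
        (tr, (values[i] if values is not None else _values_of(tr)))
        for i, tr in enumerate(traces)
        if getattr(tr, "mitosis_frames", None)
    ]
    if not usable:
        raise ValueError("no traces carry a mitosis event")
    dt = float(usable[0][0].times[1] - usable[0][0].times[0])
    lo = int(math.floor(window_h[0] / dt))
    hi = int(math.ceil(window_h[1] / dt))
    rel = np.arange(lo, hi + 1) * dt
    mat = np.full((len(usable), len(rel)), np.nan)
    ids = []
    for row, (tr, vals) in enumerate(usable):
        m = tr.mitosis_frames[anchor]
        ids.append(tr.cell_id)
        for j, off in enumerate(range(lo, hi + 1)):
            f = m + off
            if 0 <= f < len(vals):
                mat[row, j] = vals[f]
    count = np.sum(np.isfinite(mat), axis=0)
    with np.errstate(all="ignore"):
        med = np.nanmedian(mat, axis=0)
    med[count < min_count] = np.nan
    return AlignedTraceSet(relative_time=rel, matrix=mat, cell_ids=ids, median=med, count=count)


def _values_of(tr) -> np.ndarray:
    return np.asarray(tr.A if isinstance(tr, ActivityTrace) else tr.R, dtype=float)
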