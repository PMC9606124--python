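"""Reporter-trace simulation under synthesis/degradation kinetics.

The latent reporter level obeys dR/dt = s - k·R with s and k piecewise
constant over phase intervals and perturbation epochs.  Each constant-
coefficient segment is integrated analytically:

    k > 0:  R(t0 + τ) = s/k + (R(t0) - s/k) · exp(-k τ)
    k = 0:  R(t0 + τ) = R(t0) + s τ

so the noiseless trajectory is exact (no discretization error), which
makes it usable as an oracle for the downstream inference.  The measured
trace multiplies the latent by the mitotic-rounding artifact spike during
M frames and by lognormal noise of the configured CV.
"""

from __future__ import annotations

import math

import numpy as np

from ..types import DEFAULT_DT_H, KineticParams, Perturbation, PhaseSchedule, ReporterTrace


def _segment_value(r0: float, s: float, k: float, tau: float) -> float:
    if k > 0:
        ss = s / k
        return ss + (r0 - ss) * math.exp(-k * tau)
    return r0 + s * tau


def _effective_params(
    t: float,
    phase: str,
    params: KineticParams,
    perturbations: list[Perturbation],
) -> tuple[float, float]:
    """(s, k) in force during the epoch starting at time ``t``."""
    s = params.s
    eff_phase = phase
    k_scale = 1.0
    for p in perturbations:
        if t < p.t_effective - 1e-12:
            continue
        if p.s_set is not None:
            s = p.s_set
        if p.k_scale is not None:
            k_scale *= p.k_scale
        if p.phase_set is not None:
            eff_phase = p.phase_set
    k = params.k_by_phase.get(eff_phase, 0.0) * k_scale
    return s, k


def simulate_reporter_trace(
    schedule: PhaseSchedule,
    params: KineticParams,
    perturbations: list[Perturbation] | None = None,
    seed: int = 0,
    dt: float = DEFAULT_DT_H,
) -> ReporterTrace:
    """Simulate one measured reporter trace over the schedule's lifespan."""
    params.validate()
    perturbations = sorted(perturbations or [], key=lambda p: p.t_effective)
    for p in perturbations:
        if not (schedule.birth_h <= p.t_on <= schedule.death_h):
            raise ValueError(f"perturbation {p.drug} at {p.t_on} h outside trace window")

    n = int(math.floor((schedule.death_h - schedule.birth_h) / dt + 1e-9)) + 1
    times = schedule.birth_h + dt * np.arange(n)

    # breakpoints where (s, k) can change: phase edges + perturbation onsets
    breaks = sorted(
        {schedule.birth_h, schedule.death_h}
        | {iv[0] for iv in schedule.intervals}
        | {iv[1] for iv in schedule.intervals}
        | {p.t_effective for p in perturbations if p.t_effective <= schedule.death_h}
    )

    # walk segments, recording the latent value at each frame time
    latent = np.empty(n)
    phase_labels = np.empty(n, dtype=object)
    r = params.R0
    if r is None:
        # start at the steady state of the initial epoch
        s0, k0 = _effective_params(
            schedule.birth_h, schedule.phase_at(schedule.birth_h), params, perturbations
        )
        r = s0 / k0 if k0 > 0 else 0.0
    frame_i = 0
    for b0, b1 in zip(breaks, breaks[1:]):
        phase = schedule.phase_at(b0)
        s, k = _effective_params(b0, phase, params, perturbations)
        while frame_i < n and times[frame_i] <= b1 + 1e-9:
            latent[frame_i] = _segment_value(r, s, k, times[frame_i] - b0)
            phase_labels[frame_i] = phase
            frame_i += 1
        r = _segment_value(r, s, k, b1 - b0)
    while frame_i < n:  # numerical stragglers at the right edge
        latent[frame_i] = r
        phase_labels[frame_i] = schedule.phase_at(schedule.death_h)
        frame_i += 1

    mitosis_frames = sorted(
        int(round((m - schedule.birth_h) / dt)) for m in schedule.mitosis_times
    )
    mitosis_frames = [f for f in mitosis_frames if 0 <= f < n]

    measured = latent.copy()
    m_frames = np.array(
        [i for i in range(n) if phase_labels[i] == "M"]
        + [f for f in mitosis_frames],
        dtype=int,
    )
    if m_frames.size:
        measured[np.unique(m_frames)] *= params.mitotic_spike
    if params.noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = math.sqrt(math.log1p(params.noise_cv**2))
        noise = rng.lognormal(-sigma**2 / 2, sigma, size=n)
        measured = measured * noise

    trace = ReporterTrace(
        cell_id=schedule.cell_id,
        times=times,
        R=measured,
        phase=phase_labels,
        mitosis_frames=mitosis_frames,
        perturbations=perturbations,
        lineage_parent=schedule.lineage_parent,
        latent=latent,
    )
    trace.validate()
    return trace


def simulate_geminin_trace(
    schedule: PhaseSchedule,
    seed: int = 0,
    dt: float = DEFAULT_DT_H,
    rise_rate: float = 10.0,
    noise_cv: float = 0.0,
    decay_after_mitosis_h: float = 0.5,
) -> ReporterTrace:
    """APC/C-degron (Geminin) reporter: accumulates linearly from S-phase
    entry through G2/M, then is abruptly degraded at mitotic exit.

    Used as the phase-annotation channel; zero throughout G0/G1.
    """
    n = int(math.floor((schedule.death_h - schedule.birth_h) / dt + 1e-9)) + 1
    times = schedule.birth_h + dt * np.arange(n)
    g = np.zeros(n)
    level = 0.0
    for i, t in enumerate(times):
        phase = schedule.phase_at(min(t, schedule.death_h))
        if phase in ("S", "G2", "M", "SG2"):
            level += rise_rate * dt
        else:
            level = max(0.0, level - level * dt / max(decay_after_mitosis_h, dt))
            if phase in ("G0", "G1"):
                level = 0.0
        g[i] = level
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = math.sqrt(math.log1p(noise_cv**2))
        g = g * rng.lognormal(-sigma**2 / 2, sigma, size=n)
    phase_labels = np.array([schedule.phase_at(min(t, schedule.death_h)) for t in times], dtype=object)
    mitosis_frames = sorted(
        int(round((m - schedule.birth_h) / dt))
        for m in schedule.mitosis_times
        if m <= schedule.death_h
    )
    return ReporterTrace(
        cell_id=schedule.cell_id,
        times=times,
        R=g,
        phase=phase_labels,
        mitosis_frames=[f for f in mitosis_frames if f < n],
    )
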