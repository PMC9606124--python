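"""Cell-cycle phase schedule simulation.

Cells cycle G1 -> S -> G2 -> M, dividing at the end of each M interval;
phase durations are drawn per cycle from a configurable distribution
(fixed or lognormal around the given mean).  Defaults give a ~20 h cycle,
so mitoses recur roughly every 20-24 h.  A ``{"G0": hours}``-style spec
with only G0 yields a quiescent (non-dividing) schedule.
"""

from __future__ import annotations

import numpy as np

from ..types import PhaseSchedule

#: Default mean phase durations in hours (~19.6 h cycle).
DEFAULT_CYCLE = {"G1": 8.0, "S": 6.0, "G2": 5.0, "M": 0.6}

_CYCLE_ORDER = ("G1", "S", "G2", "M")


def _draw_duration(rng: np.random.Generator, mean: float, cv: float) -> float:
    if cv <= 0:
        return mean
    sigma = np.sqrt(np.log1p(cv**2))
    mu = np.log(mean) - sigma**2 / 2
    return float(rng.lognormal(mu, sigma))


def simulate_phase_schedule(
    n_cells: int,
    cycle_params: dict[str, float] | None = None,
    duration: float = 48.0,
    seed: int = 0,
    duration_cv: float = 0.0,
    lineage: bool = False,
    max_m_h: float = 1.0,
) -> list[PhaseSchedule]:
    """Simulate phase schedules for ``n_cells`` founder cells.

    Parameters
    ----------
    cycle_params
        Mean phase durations (hours).  ``{"G0": h}`` alone yields a
        quiescent schedule with a single G0 interval.
    duration
        Simulation length in hours; schedules span [0, duration].
    duration_cv
        Lognormal coefficient of variation applied to every phase draw
        (0 = deterministic durations).
    lineage
        When True, each mitosis spawns a second daughter as its own
        schedule (born at the mitosis time); the founder's schedule
        continues as the first daughter.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    cycle = dict(cycle_params or DEFAULT_CYCLE)
    if any(v <= 0 for v in cycle.values()):
        raise ValueError("phase durations must be positive")
    rng = np.random.default_rng(seed)

    quiescent = set(cycle) == {"G0"}
    schedules: list[PhaseSchedule] = []

    def build(cell_id: str, birth: float, parent: str | None) -> None:
        intervals: list[tuple[float, float, str]] = []
        mitoses: list[float] = []
        t = birth
        if quiescent:
            intervals.append((birth, duration, "G0"))
            schedules.append(PhaseSchedule(cell_id, intervals, [], birth, duration, parent))
            return
        while t < duration:
            for phase in _CYCLE_ORDER:
                if phase not in cycle:
                    continue
                d = _draw_duration(rng, cycle[phase], duration_cv)
                if phase == "M":
                    d = min(d, max_m_h)
                    if t + d > duration + 1e-9:
                        # never enter a partial mitosis: pad with the
                        # preceding phase so M intervals always complete
                        prev = intervals[-1][2] if intervals else "G2"
                        intervals.append((t, duration, prev))
                        t = duration
                        break
                end = min(t + d, duration)
                intervals.append((t, end, phase))
                completed = abs(end - (t + d)) < 1e-12
                t = end
                if phase == "M" and completed:
                    mitoses.append(t)
                    if lineage and t < duration:
                        build(f"{cell_id}.d{len(mitoses)}", t, cell_id)
                if t >= duration:
                    break
        schedules.append(PhaseSchedule(cell_id, intervals, mitoses, birth, duration, parent))

    for i in range(n_cells):
        build(f"cell{i:04d}", 0.0, None)
    for sched in schedules:
        sched.validate()
    return schedules
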