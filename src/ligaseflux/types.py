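"""Core domain types shared across the pipeline.

The central object is a :class:`ReporterTrace`: a per-cell time series of
background-corrected median nuclear reporter intensity on a uniform time
grid (default 0.2 h, i.e. 12-min imaging cadence), annotated with
cell-cycle phase labels and mitosis frames.  Kinetics are governed by the
balance equation dR/dt = s - k(t)·R, where s is the (constitutive)
synthesis rate and k the phase-dependent first-order degradation rate
driven by the ubiquitin ligase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: Recognized cell-cycle phase labels.  ``SG2`` is the merged S/G2 label
#: produced by phase annotation (the Geminin reporter cannot separate S
#: from G2); the simulator's ground truth uses the full set.
PHASES = ("G0", "G1", "S", "G2", "M", "SG2")

#: Default frame interval in hours (12-minute imaging cadence).
DEFAULT_DT_H = 0.2


@dataclass
class PhaseSchedule:
    """Ordered cell-cycle phase intervals for one cell.

    ``intervals`` is a list of ``(start_h, end_h, phase)`` tuples that tile
    ``[birth_h, death_h]`` without gaps or overlaps.  Every M interval ends
    at one of ``mitosis_times``.
    """

    cell_id: str
    intervals: list[tuple[float, float, str]]
    mitosis_times: list[float]
    birth_h: float
    death_h: float
    lineage_parent: str | None = None

    def phase_at(self, t: float) -> str:
        for start, end, phase in self.intervals:
            if start <= t < end:
                return phase
        # right edge belongs to the last interval
        if self.intervals and t == self.intervals[-1][1]:
            return self.intervals[-1][2]
        raise ValueError(f"time {t} outside schedule of {self.cell_id}")

    def validate(self) -> None:
        if not self.intervals:
            raise ValueError("empty schedule")
        if not math.isclose(self.intervals[0][0], self.birth_h):
            raise ValueError("first interval must start at birth")
        if not math.isclose(self.intervals[-1][1], self.death_h):
            raise ValueError("last interval must end at death")
        for (s0, e0, _), (s1, _, _) in zip(self.intervals, self.intervals[1:]):
            if not math.isclose(e0, s1):
                raise ValueError("intervals must tile without gaps/overlaps")
            if e0 <= s0:
                raise ValueError("degenerate interval")
        for start, end, phase in self.intervals:
            if phase not in PHASES:
                raise ValueError(f"unknown phase {phase!r}")
            if phase == "M":
                if end - start > 1.0 + 1e-9:
                    raise ValueError("M interval longer than 1 h")
                if not any(math.isclose(end, m) for m in self.mitosis_times):
                    raise ValueError("M interval must end at a mitosis time")


@dataclass
class KineticParams:
    """Synthesis/degradation parameters of the reporter.

    Defaults correspond to a reporter degraded with a 2.75 h half-life in
    G1 (k = ln2/2.75 ≈ 0.2521 /h) and a 9 h half-life in S/G2
    (k = ln2/9 ≈ 0.0770 /h).  ``mitotic_spike`` is the multiplicative
    measurement artifact applied during M frames (cell rounding / nuclear
    envelope breakdown), not a kinetic change.  ``noise_cv`` is the
    coefficient of variation of multiplicative lognormal measurement noise.
    ``R0=None`` starts the trace at the steady state s/k of the initial
    phase (or 0 when that k is 0).
    """

    s: float = 10.0
    k_by_phase: dict[str, float] = field(
        default_factory=lambda: {
            "G0": 0.30,
            "G1": 0.2521,
            "S": 0.0770,
            "G2": 0.0770,
            "SG2": 0.0770,
            "M": 0.0770,
        }
    )
    mitotic_spike: float = 1.8
    noise_cv: float = 0.05
    R0: float | None = None

    def validate(self) -> None:
        if self.s < 0:
            raise ValueError("synthesis rate must be >= 0")
        if any(k < 0 for k in self.k_by_phase.values()):
            raise ValueError("decay constants must be >= 0")
        if self.mitotic_spike < 1:
            raise ValueError("mitotic_spike must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


@dataclass
class Perturbation:
    """A drug/stimulus switch event applied at ``t_on`` (+ ``lag_h``).

    Effects compose: ``s_set`` overrides the synthesis rate, ``k_scale``
    multiplies every phase decay constant, ``phase_set`` overrides the
    effective phase (quiescence entry/exit).
    """

    drug: str
    t_on: float
    lag_h: float = 0.0
    s_set: float | None = None
    k_scale: float | None = None
    phase_set: str | None = None

    @property
    def t_effective(self) -> float:
        return self.t_on + self.lag_h

    # ---- factories for the study's canonical perturbations -------------
    @staticmethod
    def chx(t_on: float, lag_h: float = 0.0) -> "Perturbation":
        """Cycloheximide: translation block, synthesis -> 0."""
        return Perturbation("CHX", t_on, lag_h, s_set=0.0)

    @staticmethod
    def mln4924(t_on: float, residual: float = 0.0, lag_h: float = 0.0) -> "Perturbation":
        """Neddylation inhibitor: all Cullin-RING degradation scaled by
        ``residual`` (0 = complete inhibition)."""
        return Perturbation("MLN4924", t_on, lag_h, k_scale=residual)

    @staticmethod
    def sunitinib(t_on: float, k_factor: float = 3.0, lag_h: float = 1.0) -> "Perturbation":
        """RTK inhibitor: degradation accelerates within ~1 h."""
        return Perturbation("SUNITINIB", t_on, lag_h, k_scale=k_factor)

    @staticmethod
    def mitogen_withdrawal(t_on: float, lag_h: float = 0.0) -> "Perturbation":
        return Perturbation("MITOGEN_WITHDRAWAL", t_on, lag_h, phase_set="G0")

    @staticmethod
    def mitogen_stim(t_on: float, lag_h: float = 0.0) -> "Perturbation":
        return Perturbation("MITOGEN_STIM", t_on, lag_h, phase_set="G1")

    @staticmethod
    def sirna(t_on: float, k_scale: float, lag_h: float = 0.0) -> "Perturbation":
        return Perturbation("SIRNA", t_on, lag_h, k_scale=k_scale)


@dataclass
class ReporterTrace:
    """Measured per-cell reporter time series on a uniform grid."""

    cell_id: str
    times: np.ndarray  # hours, uniform grid
    R: np.ndarray  # measured intensity (a.u.)
    phase: np.ndarray  # per-frame phase label (str array)
    mitosis_frames: list[int] = field(default_factory=list)
    perturbations: list[Perturbation] = field(default_factory=list)
    lineage_parent: str | None = None
    latent: np.ndarray | None = None  # noiseless/artifact-free truth, if known
    masked_frames: np.ndarray | None = None  # indices excluded from fits

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def mask_array(self) -> np.ndarray:
        """Boolean per-frame array, True where the frame is masked."""
        m = np.zeros(self.n_frames, dtype=bool)
        if self.masked_frames is not None:
            m[np.asarray(self.masked_frames, dtype=int)] = True
        return m

    def validate(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if len(t) < 2:
            raise ValueError("trace needs >= 2 frames")
        dts = np.diff(t)
        if np.any(dts <= 0) or not np.allclose(dts, dts[0], rtol=1e-6):
            raise ValueError("times must be strictly increasing with constant step")
        if not np.all(np.isfinite(self.R)):
            raise ValueError("R must be finite")
        if any(p not in PHASES for p in np.unique(self.phase)):
            raise ValueError("unknown phase label")
        if list(self.mitosis_frames) != sorted(self.mitosis_frames):
            raise ValueError("mitosis_frames must be sorted")


@dataclass
class ActivityTrace:
    """Inferred degradation flux A(t) = s - dR/dt for one cell.

    A > 0 means active degradation.  ``k_specific`` is the level-normalized
    rate A/R (1/h), defined where R exceeds a small floor.
    """

    cell_id: str
    times: np.ndarray
    A: np.ndarray  # a.u./h, NaN on masked frames
    s_used: float
    k_specific: np.ndarray | None = None
    masked_frames: np.ndarray | None = None
    mitosis_frames: list[int] = field(default_factory=list)


@dataclass
class HalfLifeFit:
    """Log-linear fit of a cycloheximide-chase decay."""

    t_half: float  # hours; inf when no decay detected
    k_fit: float  # 1/h
    fit_window: tuple[float, float]
    r_squared: float
    n_frames: int
    no_decay: bool = False


@dataclass
class AlignedTraceSet:
    """Traces re-indexed to a common mitosis-anchored relative time axis."""

    relative_time: np.ndarray  # hours, 0 = mitosis
    matrix: np.ndarray  # (n_traces, n_timepoints), NaN off-support
    cell_ids: list[str]
    median: np.ndarray  # NaN where count < min_count
    count: np.ndarray


@dataclass
class BiasField:
    """Unit-mean, strictly positive multiplicative illumination surface."""

    values: np.ndarray
    fit_meta: dict = field(default_factory=dict)

    def validate(self) -> None:
        if np.any(self.values <= 0):
            raise ValueError("bias must be strictly positive")
        if abs(float(self.values.mean()) - 1.0) > 1e-6:
            raise ValueError("bias must have unit mean")


@dataclass
class DoseResponseFit:
    """Four-parameter logistic dose-response fit.

    response = bottom + (top - bottom) / (1 + (dose/ic50)^hill)
    """

    compound_id: str
    doses: np.ndarray
    responses: np.ndarray
    bottom: float
    top: float
    ic50_uM: float
    hill: float
    converged: bool
    residual_norm: float
    curve_class: str = "converged"  # {converged, non_converged, flat, incomplete_curve}
    fitted: np.ndarray | None = None
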