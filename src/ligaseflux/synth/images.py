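"""Synthetic microscopy rendering with ground truth.

Renders reporter traces into multichannel frames: channel 0 is the
nuclear marker (H2B; constant fill over elliptical nuclei), channel 1 the
reporter (uniform fill equal to the trace value, so the per-nucleus
median equals the trace exactly before bias/noise), channel 2 an optional
second reporter (Geminin).  Every pixel is then multiplied by a smooth,
strictly positive illumination-bias surface, mimicking the optical
vignetting that real plate imaging exhibits; an additive background level
sits under the bias, matching the correction model
``corrected = frame / bias - background``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..types import ReporterTrace


@dataclass
class NucleiLayout:
    """Geometry of the rendered field."""

    height: int = 256
    width: int = 256
    radius_px: float = 8.0
    axis_ratio: float = 0.8  # minor/major axis of the ellipse
    min_separation: float = 3.0  # in radii, for random placement
    nuclear_marker_level: float = 100.0
    background_level: float = 20.0
    positions: list[tuple[float, float]] | None = None  # (row, col) per trace
    drift_px_per_frame: float = 0.0
    orientations: list[float] | None = None
    extra: dict = field(default_factory=dict)


def _place_nuclei(n: int, layout: NucleiLayout, rng: np.random.Generator) -> np.ndarray:
    if layout.positions is not None:
        pos = np.asarray(layout.positions, dtype=float)
        if len(pos) != n:
            raise ValueError("positions must match number of traces")
        return pos
    min_d = layout.min_separation * layout.radius_px
    margin = layout.radius_px * 1.5
    placed: list[tuple[float, float]] = []
    for _ in range(n):
        for _attempt in range(5000):
            r = rng.uniform(margin, layout.height - margin)
            c = rng.uniform(margin, layout.width - margin)
            if all((r - pr) ** 2 + (c - pc) ** 2 >= min_d**2 for pr, pc in placed):
                placed.append((r, c))
                break
        else:
            raise ValueError("could not place nuclei without overlap; field too crowded")
    return np.asarray(placed)


def _ellipse_mask(
    shape: tuple[int, int], center: tuple[float, float], a: float, b: float, theta: float
) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dr = rr - center[0]
    dc = cc - center[1]
    u = dr * np.cos(theta) + dc * np.sin(theta)
    v = -dr * np.sin(theta) + dc * np.cos(theta)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def flat_bias(height: int, width: int) -> np.ndarray:
    return np.ones((height, width))


def quadratic_bias(height: int, width: int, strength: float = 0.3) -> np.ndarray:
    """Center-bright quadratic vignetting surface, unit mean."""
    rr, cc = np.mgrid[0:height, 0:width]
    y = (rr - height / 2) / (height / 2)
    x = (cc - width / 2) / (width / 2)
    surf = 1.0 + strength * (1.0 - (x**2 + y**2) / 2)
    return surf / surf.mean()


def render_image_series(
    traces: list[ReporterTrace],
    geometry: NucleiLayout | None = None,
    bias: np.ndarray | None = None,
    seed: int = 0,
    noise_sd: float = 0.0,
    geminin_traces: list[ReporterTrace] | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render traces into a (frames, channels, H, W) float stack.

    Returns the stack and a ground-truth table with one row per nucleus
    per frame (frame, cell_id, row, col, radius_px, reporter_value,
    is_mitosis, lineage_parent).
    """
    if not traces:
        raise ValueError("no traces to render")
    layout = geometry or NucleiLayout()
    n_frames = traces[0].n_frames
    if any(t.n_frames != n_frames for t in traces):
        raise ValueError("all traces must share the frame grid")
    if bias is None:
        bias = flat_bias(layout.height, layout.width)
    if bias.shape != (layout.height, layout.width):
        raise ValueError("bias shape must match the frame size")
    if np.any(bias <= 0):
        raise ValueError("bias must be strictly positive")

    rng = np.random.default_rng(seed)
    pos0 = _place_nuclei(len(traces), layout, rng)
    margin = layout.radius_px
    if np.any(pos0 < margin) or np.any(pos0[:, 0] > layout.height - margin) or np.any(
        pos0[:, 1] > layout.width - margin
    ):
        raise ValueError("nucleus outside frame bounds")
    thetas = (
        np.asarray(layout.orientations)
        if layout.orientations is not None
        else rng.uniform(0, np.pi, size=len(traces))
    )

    n_channels = 3 if geminin_traces is not None else 2
    stack = np.empty((n_frames, n_channels, layout.height, layout.width))
    truth_rows = []
    a = layout.radius_px
    b = layout.radius_px * layout.axis_ratio
    for f in range(n_frames):
        marker = np.zeros((layout.height, layout.width))
        reporter = np.zeros_like(marker)
        geminin = np.zeros_like(marker)
        for i, tr in enumerate(traces):
            drift = layout.drift_px_per_frame * f
            center = (pos0[i, 0] + drift, pos0[i, 1] + drift)
            mask = _ellipse_mask(marker.shape, center, a, b, thetas[i])
            marker[mask] = layout.nuclear_marker_level
            reporter[mask] = tr.R[f]
            if geminin_traces is not None:
                geminin[mask] = geminin_traces[i].R[f]
            truth_rows.append(
                {
                    "frame": f,
                    "cell_id": tr.cell_id,
                    "row": center[0],
                    "col": center[1],
                    "radius_px": a,
                    "reporter_value": tr.R[f],
                    "is_mitosis": f in tr.mitosis_frames,
                    "lineage_parent": tr.lineage_parent,
                }
            )
        channels = [marker, reporter] + ([geminin] if geminin_traces is not None else [])
        for c, img in enumerate(channels):
            frame = (img + layout.background_level) * bias
            if noise_sd > 0:
                frame = frame + rng.normal(0, noise_sd, size=frame.shape)
            stack[f, c] = frame
    return stack, pd.DataFrame(truth_rows)
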