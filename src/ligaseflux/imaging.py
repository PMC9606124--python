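"""Quantitative image analysis: illumination flattening, nuclear
segmentation, tracking with division detection, and median-nuclear-
intensity trace extraction.

The correction model is multiplicative vignetting over an additive
background: a raw frame is ``bias × (background + signal)``.  The bias
surface is estimated empirically from background areas (pixels below a
low intensity percentile) pooled across sampled frames and fit with a
low-order 2D polynomial; frames are divided by the unit-mean surface and
a robust global background (low percentile of the flattened frame) is
subtracted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial.distance import cdist
from skimage import feature, filters, measure, segmentation

from .types import DEFAULT_DT_H, BiasField, ReporterTrace


@dataclass
class LabelMap:
    """Integer label image for one frame plus per-label geometry."""

    labels: np.ndarray  # int grid, 0 = background
    table: pd.DataFrame  # columns: label, row, col, area

    @property
    def n_labels(self) -> int:
        return len(self.table)


@dataclass
class SegmentationParams:
    smooth_sigma: float = 2.0
    min_area: int = 40
    max_area: int = 10_000
    split_min_distance: int = 7  # px between watershed seeds
    threshold: float | None = None  # None = Otsu


# --------------------------------------------------------------------------
# illumination bias
# --------------------------------------------------------------------------

def _poly_design(rows: np.ndarray, cols: np.ndarray, shape: tuple[int, int], order: int) -> np.ndarray:
    # normalized coordinates keep the normal equations well conditioned
    y = rows / max(shape[0] - 1, 1) - 0.5
    x = cols / max(shape[1] - 1, 1) - 0.5
    terms = [np.ones_like(y)]
    for total in range(1, order + 1):
        for i in range(total + 1):
            terms.append(y ** (total - i) * x**i)
    return np.column_stack(terms)


def estimate_illumination_bias(
    frames: np.ndarray | list[np.ndarray],
    background_percentile: float = 10.0,
    order: int = 2,
) -> BiasField:
    """Fit a smooth low-order surface to background pixels pooled across
    frames; returns the unit-mean multiplicative bias field.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.size == 0:
        raise ValueError("need at least one frame")
    shape = frames.shape[1:]
    rows_all, cols_all, vals_all = [], [], []
    for frame in frames:
        thresh = np.percentile(frame, background_percentile)
        mask = frame <= thresh
        if not mask.any():
            continue
        rr, cc = np.nonzero(mask)
        rows_all.append(rr)
        cols_all.append(cc)
        vals_all.append(frame[mask])
    if not rows_all:
        raise ValueError("no background pixels under the selector")
    rr = np.concatenate(rows_all)
    cc = np.concatenate(cols_all)
    vals = np.concatenate(vals_all)

    design = _poly_design(rr.astype(float), cc.astype(float), shape, order)
    coef, *_ = np.linalg.lstsq(design, vals, rcond=None)
    resid = float(np.sqrt(np.mean((design @ coef - vals) ** 2)))

    gr, gc = np.mgrid[0 : shape[0], 0 : shape[1]]
    surface = (_poly_design(gr.ravel().astype(float), gc.ravel().astype(float), shape, order) @ coef).reshape(shape)
    if np.any(surface <= 0):
        raise ValueError("fitted bias surface not strictly positive")
    surface = surface / surface.mean()
    return BiasField(values=surface, fit_meta={"order": order, "rms_residual": resid, "n_pixels": len(vals)})


def correct_frame(
    frame: np.ndarray,
    bias: BiasField | np.ndarray,
    background_percentile: float = 5.0,
) -> np.ndarray:
    """Flatten by the bias and subtract the global background (a robust
    low percentile of the flattened frame).  Output is not clipped; small
    negatives are expected in background regions."""
    values = bias.values if isinstance(bias, BiasField) else np.asarray(bias)
    if frame.shape != values.shape:
        raise ValueError(f"frame {frame.shape} vs bias {values.shape} shape mismatch")
    flat = frame / values
    return flat - np.percentile(flat, background_percentile)


# --------------------------------------------------------------------------
# segmentation
# --------------------------------------------------------------------------

def segment_nuclei(frame: np.ndarray, params: SegmentationParams | None = None) -> LabelMap:
    """Threshold-based nuclear segmentation with distance-transform
    splitting of touching nuclei."""
    p = params or SegmentationParams()
    smoothed = filters.gaussian(frame.astype(float), sigma=p.smooth_sigma, preserve_range=True)
    if p.threshold is not None:
        thresh = p.threshold
    else:
        finite = smoothed[np.isfinite(smoothed)]
        if finite.size == 0 or np.ptp(finite) < 1e-12:
            return LabelMap(np.zeros(frame.shape, dtype=np.int32), _empty_table())
        thresh = filters.threshold_otsu(finite)
    binary = smoothed > thresh
    if not binary.any():
        return LabelMap(np.zeros(frame.shape, dtype=np.int32), _empty_table())

    # split touching nuclei: distance-transform maxima seed a watershed
    distance = ndimage.distance_transform_edt(binary)
    # light smoothing removes ridge plateaus that would seed false splits
    distance = ndimage.gaussian_filter(distance, sigma=1.0)
    peak_idx = feature.peak_local_max(
        distance, min_distance=p.split_min_distance, labels=measure.label(binary)
    )
    markers = np.zeros(frame.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peak_idx, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        labels = measure.label(binary).astype(np.int32)
    else:
        labels = segmentation.watershed(-distance, markers, mask=binary).astype(np.int32)

    # size filter and relabel consecutively
    props = measure.regionprops(labels)
    keep = {pr.label for pr in props if p.min_area <= pr.area <= p.max_area}
    filtered = np.where(np.isin(labels, list(keep)), labels, 0)
    labels, _, _ = segmentation.relabel_sequential(filtered)
    labels = labels.astype(np.int32)

    rows = [
        {"label": pr.label, "row": pr.centroid[0], "col": pr.centroid[1], "area": pr.area}
        for pr in measure.regionprops(labels)
    ]
    table = pd.DataFrame(rows) if rows else _empty_table()
    return LabelMap(labels, table)


def _empty_table() -> pd.DataFrame:
    return pd.DataFrame(columns=["label", "row", "col", "area"])


# --------------------------------------------------------------------------
# tracking
# --------------------------------------------------------------------------

def track_nuclei(
    labelmaps: list[LabelMap],
    max_disp: float = 15.0,
    division_radius_factor: float = 1.5,
) -> nx.DiGraph:
    """Greedy mutual-nearest-centroid frame-to-frame linking.

    Nodes are ``(frame, label)`` with ``row``/``col`` attributes.  An
    object that disappears while two unlinked objects appear nearby in
    the next frame becomes a division node with exactly two children.
    """
    if max_disp <= 0:
        raise ValueError("max_disp must be positive")
    g = nx.DiGraph()
    for f, lm in enumerate(labelmaps):
        for rec in lm.table.itertuples(index=False):
            g.add_node((f, int(rec.label)), row=float(rec.row), col=float(rec.col), frame=f)

    for f in range(len(labelmaps) - 1):
        a = labelmaps[f].table
        b = labelmaps[f + 1].table
        if a.empty or b.empty:
            continue
        pa = a[["row", "col"]].to_numpy(float)
        pb = b[["row", "col"]].to_numpy(float)
        d = cdist(pa, pb)
        # mutual nearest neighbours within max_disp
        nn_ab = d.argmin(axis=1)
        nn_ba = d.argmin(axis=0)
        matched_a, matched_b = set(), set()
        for i, j in enumerate(nn_ab):
            if nn_ba[j] == i and d[i, j] <= max_disp:
                g.add_edge(
                    (f, int(a.iloc[i]["label"])), (f + 1, int(b.iloc[j]["label"])),
                    distance=float(d[i, j]),
                )
                matched_a.add(i)
                matched_b.add(j)
        # division: a parent whose two daughters appear in the next frame.
        # Mutual matching links the parent to one daughter; the other
        # shows up as an orphan newcomer near the parent.  An unmatched
        # parent with two orphan newcomers nearby is also a division.
        div_radius = division_radius_factor * max_disp
        free_b = [j for j in range(len(b)) if j not in matched_b]
        for i in range(len(a)):
            if i in matched_a:
                continue
            near = sorted((d[i, j], j) for j in free_b if d[i, j] <= div_radius)
            if len(near) >= 2:
                for dist_ij, j in near[:2]:
                    g.add_edge(
                        (f, int(a.iloc[i]["label"])), (f + 1, int(b.iloc[j]["label"])),
                        distance=float(dist_ij), division=True,
                    )
                    free_b.remove(j)
        for j in list(free_b):
            cands = sorted(
                (d[i, j], i)
                for i in range(len(a))
                if d[i, j] <= div_radius
                and g.out_degree((f, int(a.iloc[i]["label"]))) == 1
            )
            if not cands:
                continue
            dist_ij, i = cands[0]
            parent = (f, int(a.iloc[i]["label"]))
            g.add_edge(
                parent, (f + 1, int(b.iloc[j]["label"])),
                distance=float(dist_ij), division=True,
            )
            for child in g.successors(parent):
                g.edges[parent, child]["division"] = True
            free_b.remove(j)
    return g


def validate_track_graph(g: nx.DiGraph) -> None:
    """Structural invariants: ≤1 parent per node, 1-frame edges, and
    division nodes with exactly two children."""
    for node in g.nodes:
        if g.in_degree(node) > 1:
            raise ValueError(f"node {node} has multiple parents")
        succ = list(g.successors(node))
        if len(succ) > 2:
            raise ValueError(f"node {node} has more than two children")
        if len(succ) == 2 and not all(g.edges[node, s].get("division") for s in succ):
            raise ValueError(f"two-child node {node} not marked as division")
        for s in succ:
            if s[0] - node[0] != 1:
                raise ValueError(f"edge {node}->{s} spans more than one frame")


# --------------------------------------------------------------------------
# trace extraction
# --------------------------------------------------------------------------

def extract_traces(
    reporter_frames: np.ndarray | list[np.ndarray],
    labelmaps: list[LabelMap],
    trackgraph: nx.DiGraph,
    dt: float = DEFAULT_DT_H,
    min_length: int = 2,
) -> list[ReporterTrace]:
    """One trace per root-to-leaf track path, following the lower-label
    daughter at divisions; the per-frame value is the median reporter
    intensity under the nucleus label."""
    reporter_frames = [np.asarray(f) for f in reporter_frames]
    roots = [n for n in trackgraph.nodes if trackgraph.in_degree(n) == 0]
    traces: list[ReporterTrace] = []
    for root in sorted(roots):
        path = [root]
        mitosis_frames: list[int] = []
        node = root
        while True:
            succ = sorted(trackgraph.successors(node))
            if not succ:
                break
            if len(succ) == 2:
                mitosis_frames.append(node[0])
            node = succ[0]  # deterministic: follow the lower label
            path.append(node)
        if len(path) < min_length:
            continue
        frames = [n[0] for n in path]
        values = np.empty(len(path))
        flagged_missing = []
        for i, (f, label) in enumerate(path):
            mask = labelmaps[f].labels == label
            if not mask.any():
                values[i] = np.nan
                flagged_missing.append(i)
            else:
                values[i] = float(np.median(reporter_frames[f][mask]))
        times = np.asarray(frames, dtype=float) * dt
        trace = ReporterTrace(
            cell_id=f"track_{root[0]:03d}_{root[1]:03d}",
            times=times,
            R=values,
            phase=np.array(["G1"] * len(path), dtype=object),
            mitosis_frames=mitosis_frames,
            masked_frames=np.asarray(flagged_missing, dtype=int) if flagged_missing else None,
        )
        traces.append(trace)
    return traces
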