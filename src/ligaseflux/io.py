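"""CSV / TIFF interchange for traces, plates and image stacks."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .types import ReporterTrace


def traces_to_frame(traces: list[ReporterTrace]) -> pd.DataFrame:
    """Long-format trace table: cell_id, frame, time_h, intensity,
    phase, is_mitosis, masked."""
    rows = []
    for tr in traces:
        mask = tr.mask_array()
        for f in range(tr.n_frames):
            rows.append(
                {
                    "cell_id": tr.cell_id,
                    "frame": f,
                    "time_h": float(tr.times[f]),
                    "intensity": float(tr.R[f]),
                    "phase": str(tr.phase[f]),
                    "is_mitosis": f in tr.mitosis_frames,
                    "masked": bool(mask[f]),
                }
            )
    return pd.DataFrame(rows)


def frame_to_traces(df: pd.DataFrame) -> list[ReporterTrace]:
    traces = []
    for cell_id, sub in df.groupby("cell_id", sort=True):
        sub = sub.sort_values("frame")
        masked = np.nonzero(sub["masked"].to_numpy())[0] if "masked" in sub else np.array([], int)
        traces.append(
            ReporterTrace(
                cell_id=str(cell_id),
                times=sub["time_h"].to_numpy(float),
                R=sub["intensity"].to_numpy(float),
                phase=sub["phase"].to_numpy(object),
                mitosis_frames=list(np.nonzero(sub["is_mitosis"].to_numpy())[0]),
                masked_frames=masked if masked.size else None,
            )
        )
    return traces


def write_traces_csv(traces: list[ReporterTrace], path: str | Path) -> None:
    traces_to_frame(traces).to_csv(path, index=False)


def read_traces_csv(path: str | Path) -> list[ReporterTrace]:
    return frame_to_traces(pd.read_csv(path))


def write_image_stack(stack: np.ndarray, path: str | Path) -> None:
    """(frames, channels, H, W) stack as OME-TIFF, channel order
    CFP/YFP/RFP."""
    tifffile.imwrite(
        path,
        stack.astype(np.float32),
        ome=True,
        metadata={"axes": "TCYX"},
    )


def read_image_stack(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(path)
    if arr.ndim == 3:
        arr = arr[:, None]
    return arr


def write_plate_csv(plate: pd.DataFrame, path: str | Path) -> None:
    plate.to_csv(path, index=False)


def read_plate_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
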