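"""Paired live-imaging / fixed-staining single-cell data.

Emulates the fix-and-stain experiment: cells are imaged live (yielding a
terminal inferred activity), then fixed and immunostained for the ligase
protein.  The latent (activity, protein) pair is bivariate normal with a
target correlation ``rho_true``; marginals are affine, so the Pearson
correlation of the emitted columns equals ``rho_true`` exactly in
expectation.  Fixed-cell centroids are jittered relative to live
centroids to exercise live-to-fixed matching.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def simulate_live_fixed_pairs(
    n_cells: int,
    activity_dist: tuple[float, float] = (5.0, 1.5),
    protein_dist: tuple[float, float] = (100.0, 25.0),
    rho_true: float = 0.0,
    seed: int = 0,
    field_px: int = 1024,
    jitter_px: float = 2.0,
    min_separation_px: float = 5.0,
) -> pd.DataFrame:
    """Columns: cell_id, activity, protein_level, live_row, live_col,
    fixed_row, fixed_col."""
    if abs(rho_true) > 1:
        raise ValueError("|rho_true| must be <= 1")
    if n_cells < 3:
        raise ValueError("need at least 3 cells")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_cells, 2))
    z2 = rho_true * z[:, 0] + np.sqrt(max(0.0, 1 - rho_true**2)) * z[:, 1]
    activity = activity_dist[0] + activity_dist[1] * z[:, 0]
    protein = protein_dist[0] + protein_dist[1] * z2

    # rejection-free grid-jittered placement keeps cells separated
    n_side = int(np.ceil(np.sqrt(n_cells)))
    pitch = field_px / n_side
    idx = rng.permutation(n_side * n_side)[:n_cells]
    rows = (idx // n_side + 0.5) * pitch
    cols = (idx % n_side + 0.5) * pitch
    jitter_live = rng.uniform(-1, 1, (n_cells, 2)) * max(
        0.0, (pitch - min_separation_px) / 2 - jitter_px
    )
    live = np.column_stack([rows, cols]) + jitter_live
    fixed = live + rng.uniform(-1, 1, (n_cells, 2)) * jitter_px

    return pd.DataFrame(
        {
            "cell_id": [f"cell{i:05d}" for i in range(n_cells)],
            "activity": activity,
            "protein_level": protein,
            "live_row": live[:, 0],
            "live_col": live[:, 1],
            "fixed_row": fixed[:, 0],
            "fixed_col": fixed[:, 1],
        }
    )
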