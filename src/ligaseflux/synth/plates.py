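"""1536-well screening-plate simulation.

Each compound well contains cells at the reporter steady state; the
compound rescales the degradation constant (``k_scale``) and/or the
synthesis rate (``s_scale``) and the plate is read after ``read_time``
hours (default 6 h, the screening incubation).  Luminescence is the
reporter level at read time times a gain, plus an instrument baseline.
Negative control wells (media only) emit baseline-only signal; neutral
controls (cells + DMSO) carry unmodified kinetics.  Defaults place the
neutral median near 1000 a.u.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

ROWS_1536 = 32
COLS_1536 = 48


@dataclass
class PlateKinetics:
    s: float = 10.0
    k: float = 0.25
    gain: float = 23.75
    baseline: float = 50.0


def default_layout_1536(compounds: dict[str, tuple[int, int]] | None = None) -> pd.DataFrame:
    """Role map: column 0 = neutral (32 wells), column 1 = negative (32
    wells), remaining wells = compound (or empty)."""
    rows = []
    comp_at = {v: k for k, v in (compounds or {}).items()}
    for r in range(ROWS_1536):
        for c in range(COLS_1536):
            if c == 0:
                role, comp = "neutral", None
            elif c == 1:
                role, comp = "negative", None
            else:
                role = "compound"
                comp = comp_at.get((r, c))
            rows.append({"row": r, "col": c, "role": role, "compound_id": comp})
    return pd.DataFrame(rows)


def _level_at(s: float, k: float, r0: float, t: float) -> float:
    if k > 0:
        ss = s / k
        return ss + (r0 - ss) * math.exp(-k * t)
    return r0 + s * t


def simulate_screen_plate(
    layout: pd.DataFrame,
    effect_table: pd.DataFrame | None = None,
    read_time: float = 6.0,
    noise_cv: float = 0.0,
    seed: int = 0,
    kinetics: PlateKinetics | None = None,
    plate_id: str = "plate01",
) -> pd.DataFrame:
    """Simulate one plate read.

    ``effect_table`` columns: compound_id, k_scale, s_scale (missing
    columns default to 1); compounds present in the table must exist in
    the layout.  Returns the layout with ``lum`` and ``conc_uM`` columns
    added.
    """
    kin = kinetics or PlateKinetics()
    roles = set(layout["role"])
    if "neutral" not in roles or "negative" not in roles:
        raise ValueError("layout needs at least one neutral and one negative well")
    effects: dict[str, tuple[float, float]] = {}
    if effect_table is not None:
        known = set(layout["compound_id"].dropna())
        for _, row in effect_table.iterrows():
            cid = row["compound_id"]
            if cid not in known:
                raise ValueError(f"compound {cid!r} not placed in any well")
            effects[cid] = (row.get("k_scale", 1.0), row.get("s_scale", 1.0))

    rng = np.random.default_rng(seed)
    r0 = kin.s / kin.k if kin.k > 0 else 0.0
    lum = np.empty(len(layout))
    for i, row in enumerate(layout.itertuples(index=False)):
        if row.role == "negative":
            signal = 0.0
        else:
            k_scale, s_scale = effects.get(getattr(row, "compound_id", None), (1.0, 1.0))
            signal = _level_at(kin.s * s_scale, kin.k * k_scale, r0, read_time)
        value = kin.baseline + kin.gain * signal
        if noise_cv > 0:
            sigma = math.sqrt(math.log1p(noise_cv**2))
            value *= rng.lognormal(-sigma**2 / 2, sigma)
        lum[i] = value
    out = layout.copy()
    out["lum"] = lum
    out["plate_id"] = plate_id
    if "conc_uM" not in out.columns:
        out["conc_uM"] = np.where(out["compound_id"].notna(), 13.0, np.nan)
    return out
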