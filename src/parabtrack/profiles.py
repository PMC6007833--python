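"""Axial fluorescence profiles: smoothing, heatmap normalisation, ParA maximum.

An :class:`AxialProfile` is one cell's 1-D intensity trace along its long
axis at one frame, for one channel.  Axial positions are reported in
micrometres from the cell's *new* pole (the end created at the most recent
division), which is the orientation convention used throughout: kymographs
are drawn with the new pole at the bottom, and the ParA maximum and ParB
focus positions are all new-pole-anchored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

logger = logging.getLogger(__name__)


@dataclass
class AxialProfile:
    cell_id: int
    frame: int
    channel: str                # "parA" | "parB"
    intensities: np.ndarray
    pixel_size: float           # um / px
    new_pole_end: str = "left"  # "left" | "right" | "unknown"
    cell_length_um: float | None = None  # true axial length, if known

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.size < 3:
            raise ValueError("profile needs at least 3 pixels")
        if not np.all(np.isfinite(self.intensities)) or np.any(self.intensities < 0):
            raise ValueError("intensities must be finite and non-negative")

    @property
    def n_pixels(self) -> int:
        return int(self.intensities.size)

    @property
    def length_um(self) -> float:
        """Axial length used for pole-relative positions.

        The recorded cell length when available (the sampled grid may fall
        up to one pixel short of the true pole), else the grid span.
        """
        if self.cell_length_um is not None:
            return float(self.cell_length_um)
        return (self.n_pixels - 1) * self.pixel_size

    def pixel_positions_um(self) -> np.ndarray:
        """Per-pixel axial positions in um from the new pole.

        Pixel i sits at i * pixel_size from the left end (0-based grid).
        An unknown pole falls back to the left end so positions are still
        well defined (they are then only consistent up to an axis flip).
        """
        pos = np.arange(self.n_pixels) * self.pixel_size
        if self.new_pole_end == "right":
            return pos[::-1].copy()
        return pos


def profiles_from_table(
    table: pd.DataFrame,
    cell_table: pd.DataFrame,
    pixel_size: float,
    channel: str,
) -> list[AxialProfile]:
    """Materialise :class:`AxialProfile` objects from the long-format CSV.

    ``table`` columns: cell_id, frame, pixel_index, parA_intensity,
    parB_intensity; pole orientation is taken from ``cell_table``.
    """
    col = {"parA": "parA_intensity", "parB": "parB_intensity"}[channel]
    poles = (cell_table.drop_duplicates("cell_id")
             .set_index("cell_id")["new_pole_end"].to_dict())
    lengths = {
        (int(r.cell_id), int(r.frame)): float(r.length_um)
        for r in cell_table.itertuples()
    }
    out = []
    for (cid, frame), g in table.groupby(["cell_id", "frame"], sort=True):
        g = g.sort_values("pixel_index")
        out.append(AxialProfile(
            cell_id=int(cid), frame=int(frame), channel=channel,
            intensities=g[col].to_numpy(),
            pixel_size=pixel_size,
            new_pole_end=poles.get(int(cid), "unknown"),
            cell_length_um=lengths.get((int(cid), int(frame))),
        ))
    return out


def smooth_profile(profile: AxialProfile, sigma_px: float = 2.0) -> AxialProfile:
    """Gaussian-smooth the trace along the axis (reflective boundaries).

    Reflection avoids the edge dimming that zero-padding would introduce,
    which would otherwise bias pole-proximal maxima inward.
    """
    if sigma_px <= 0:
        raise ValueError("sigma_px must be positive")
    sm = gaussian_filter1d(profile.intensities, sigma_px, mode="reflect")
    return replace(profile, intensities=np.clip(sm, 0.0, None))


def para_maximum(profile: AxialProfile) -> float:
    """Position of the ParA intensity maximum, in um from the new pole.

    Ties are broken toward the new pole.  A flat profile has no defined
    maximum and returns NaN (such frames are excluded from the distance,
    MSD and velocity analyses).
    """
    vals = profile.intensities
    if np.ptp(vals) == 0:
        return float("nan")
    winners = np.flatnonzero(vals == vals.max())
    idx = winners[-1] if profile.new_pole_end == "right" else winners[0]
    pos = idx * profile.pixel_size
    if profile.new_pole_end == "right":
        pos = profile.length_um - pos
    return float(pos)


@dataclass
class ParaHeatmap:
    """Lifetime-normalised ParA profiles of one cell, new pole at index 0.

    ``profiles[i]`` is the frame-``frames[i]`` trace divided by the single
    maximum over the whole birth-to-division lifetime, oriented so index 0
    is the new-pole end.  ``max_positions_um`` is the per-frame argmax in
    um from the new pole (NaN for flat frames).
    """

    cell_id: int
    frames: np.ndarray
    profiles: list[np.ndarray]
    max_positions_um: np.ndarray
    pixel_size: float
    all_zero: bool = False


def normalize_para_heatmap(profiles: list[AxialProfile]) -> ParaHeatmap:
    """Normalise one cell's ParA profiles to the lifetime-wide maximum.

    Every pixel of every frame is divided by the single largest intensity
    observed across the cell's whole lifetime, so the heatmap has exactly
    one global value of 1 (absent ties).  All-zero signal yields an
    all-zero heatmap and sets the ``all_zero`` flag.
    """
    if not profiles:
        raise ValueError("need at least one frame")
    ids = {p.cell_id for p in profiles}
    if len(ids) != 1:
        raise ValueError("profiles must all belong to one cell")
    ordered = sorted(profiles, key=lambda p: p.frame)
    peak = max(float(p.intensities.max()) for p in ordered)
    all_zero = peak <= 0
    if all_zero:
        logger.warning("cell %d has all-zero ParA signal", ordered[0].cell_id)
        peak = 1.0
    oriented, max_pos = [], []
    for p in ordered:
        vals = p.intensities / peak
        if p.new_pole_end == "right":
            vals = vals[::-1].copy()
        oriented.append(vals)
        max_pos.append(para_maximum(p))
    return ParaHeatmap(
        cell_id=ordered[0].cell_id,
        frames=np.array([p.frame for p in ordered], dtype=int),
        profiles=oriented,
        max_positions_um=np.asarray(max_pos, dtype=float),
        pixel_size=ordered[0].pixel_size,
        all_zero=all_zero,
    )


def para_maxima_table(
    para_profiles: list[AxialProfile], sigma_px: float = 2.0
) -> pd.DataFrame:
    """Smoothed ParA maximum per (cell, frame): cell_id, frame, position_um."""
    rows = [
        {"cell_id": p.cell_id, "frame": p.frame,
         "position_um": para_maximum(smooth_profile(p, sigma_px))}
        for p in para_profiles
    ]
    return pd.DataFrame(rows, columns=["cell_id", "frame", "position_um"])
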