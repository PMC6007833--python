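"""Ground-truthed synthetic lineages of asymmetrically dividing rod cells.

This module emulates the data-generating process the downstream analysis
assumes: exponentially elongating cells imaged at a fixed frame interval,
dividing asymmetrically once they reach a threshold length; a ParA intensity
gradient peaked near the new pole that relocates to the incipient septum
just before division; and 1-4 ParB foci per cell whose axial motion is
sub-diffusive (fractional Gaussian) near the ParA maximum and directed
toward the old pole far from it.  Everything is rendered as Gaussian spots
and bumps on a noisy 1-D pixel grid, and every latent quantity (true focus
positions, true ParA maximum, division planes, focus splits) is recorded as
ground truth so each analysis stage can be scored exactly.

The fractional-Gaussian-noise generator here is also used directly to
produce the sub-diffusive / Brownian / ballistic test tracks whose MSD
exponents (2H, 1 and 2) anchor the diffusion-regime classification.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SimParams",
    "GroundTruth",
    "fgn_increments",
    "simulate_tracks",
    "simulate_ou_series",
    "simulate_lineage",
    "render_profiles",
    "write_dataset",
]


@dataclass
class SimParams:
    """Parameters of the synthetic movie.

    Lengths in micrometres, times in hours, intensities in arbitrary camera
    units.  ``division_asymmetry`` is the larger daughter's share of the
    parent length; ``parA_peak_frac`` positions the ParA maximum as a
    fraction of cell length from the new pole; ``near_regime_hurst`` is the
    Hurst parameter of the sub-diffusive focus motion near the ParA maximum
    (MSD exponent 2H).
    """

    pixel_size: float = 0.1            # um per pixel
    frame_interval: float = 0.25       # h (15-min imaging cadence)
    elongation_rate: float = 0.23      # 1/h exponential elongation (~3 h doubling)
    division_length: float = 5.0       # um length triggering division
    division_asymmetry: float = 0.6    # larger daughter's share of parent
    parA_peak_frac: float = 0.2        # ParA max position, fraction from new pole
    parA_peak_width: float = 0.4       # um, sd of the ParA bump
    parA_amplitude: float = 300.0
    parA_baseline: float = 50.0
    parB_amplitude: float = 250.0
    parB_baseline: float = 30.0
    spot_sigma: float = 0.15           # um, sd of a rendered ParB spot
    noise_sd: float = 6.0              # additive Gaussian pixel noise
    near_regime_hurst: float = 0.2     # MSD exponent 2H = 0.4 near ParA
    far_regime_speed: float = 0.5      # um/h directed speed toward old pole
    regime_switch_distance: float = 1.5  # um from ParA max where transport engages
    step_scale_um: float = 0.05        # um, per-frame fGn step scale of focus motion
    division_jitter_sd: float = 0.03   # sd of truncated-Gaussian asymmetry jitter
    split_length_frac: float = 0.68    # focus splits when L >= frac * division_length
    split_offset_um: float = 0.7       # initial half-separation of sibling foci
    initial_length_um: float = 3.0     # root cell birth length
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if not (0.5 <= self.division_asymmetry < 1):
            raise ValueError("division_asymmetry must be in [0.5, 1)")
        if not (0 < self.near_regime_hurst < 1):
            raise ValueError("near_regime_hurst must be in (0, 1)")
        if self.division_length <= self.initial_length_um:
            raise ValueError("division_length must exceed the initial length")


@dataclass
class GroundTruth:
    """Latent state of a simulated movie, the oracle for every stage.

    Positions are stored both in left-anchored cell coordinates (used for
    rendering) and as distances from the cell's new pole (the analysis
    convention).
    """

    cells: pd.DataFrame        # frame, time_h, cell_id, parent_id, length_um, new_pole_end
    foci: pd.DataFrame         # frame, cell_id, focus_id, x_left_um, position_um
    para_max: pd.DataFrame     # frame, cell_id, x_left_um, position_um
    divisions: pd.DataFrame    # frame, parent_id, daughter_new_side, daughter_old_side,
    #                            plane_left_um, larger_daughter, max_inheritor
    splits: pd.DataFrame       # frame, cell_id, parent_focus_id, child_near_id, child_far_id

    def to_json(self, path: str | Path) -> None:
        payload = {
            name: getattr(self, name).to_dict(orient="records")
            for name in ("cells", "foci", "para_max", "divisions", "splits")
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(**{k: pd.DataFrame(v) for k, v in payload.items()})


# ---------------------------------------------------------------------------
# Motion-model primitives
# ---------------------------------------------------------------------------

def fgn_autocovariance(lags: np.ndarray, hurst: float, step_scale: float) -> np.ndarray:
    """Closed-form autocovariance of fractional Gaussian noise.

    gamma(k) = (scale^2 / 2) (|k+1|^{2H} - 2|k|^{2H} + |k-1|^{2H});
    the corresponding cumulative motion has MSD = scale^2 * k^{2H}.
    """
    k = np.abs(np.asarray(lags, dtype=float))
    h2 = 2.0 * hurst
    return 0.5 * step_scale**2 * (
        np.abs(k + 1) ** h2 - 2 * k**h2 + np.abs(k - 1) ** h2
    )


def _fgn_cholesky(n_steps: int, hurst: float, step_scale: float) -> np.ndarray:
    cov = fgn_autocovariance(
        np.abs(np.subtract.outer(np.arange(n_steps), np.arange(n_steps))),
        hurst,
        step_scale,
    )
    # jitter guards round-off for H near 1; tracks are short so O(n^3) is fine
    return np.linalg.cholesky(cov + 1e-12 * step_scale**2 * np.eye(n_steps))


def fgn_increments(
    n_tracks: int, n_steps: int, hurst: float, step_scale: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n_tracks`` fGn increment series of length ``n_steps``.

    Exact sampling by Cholesky factorisation of the closed-form covariance.
    """
    if not (0 < hurst < 1):
        raise ValueError("hurst must be in (0, 1)")
    L = _fgn_cholesky(n_steps, hurst, step_scale)
    z = rng.standard_normal((n_steps, n_tracks))
    return (L @ z).T


def simulate_tracks(
    regime: str,
    n_tracks: int,
    n_steps: int,
    dt: float,
    step_scale: float,
    seed: int,
    *,
    hurst: float | None = None,
    speed: float | None = None,
) -> np.ndarray:
    """Generate 1-D position series for one of the three motion classes.

    ``regime`` is ``"subdiffusive"`` (requires ``hurst``; fractional
    Gaussian increments, MSD exponent 2H), ``"brownian"`` (independent
    Gaussian increments, exponent 1) or ``"ballistic"`` (noise-free constant
    drift at ``speed``, exponent 2).  Positions start at 0; shape is
    ``(n_tracks, n_steps)``.
    """
    if n_steps < 3:
        raise ValueError("n_steps must be >= 3")
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = np.random.default_rng(seed)
    if regime == "ballistic":
        if speed is None:
            raise ValueError("ballistic regime requires speed")
        t = np.arange(n_steps) * dt
        return np.tile(speed * t, (n_tracks, 1))
    if regime == "brownian":
        inc = rng.standard_normal((n_tracks, n_steps - 1)) * step_scale
    elif regime == "subdiffusive":
        if hurst is None:
            raise ValueError("subdiffusive regime requires hurst")
        inc = fgn_increments(n_tracks, n_steps - 1, hurst, step_scale, rng)
    else:
        raise ValueError(f"unknown regime {regime!r}")
    pos = np.zeros((n_tracks, n_steps))
    pos[:, 1:] = np.cumsum(inc, axis=1)
    return pos


def simulate_ou_series(
    n_tracks: int,
    n_steps: int,
    *,
    mean: float = 1.0,
    reversion: float = 0.5,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> np.ndarray:
    """Discrete mean-reverting (Ornstein-Uhlenbeck-style) series.

    x_{t+1} = x_t + reversion * (mean - x_t) + N(0, noise_sd); the MSD of
    such confined motion saturates, so its fitted power-law exponent falls
    below 1 — the confined end of the regime spectrum.
    """
    rng = np.random.default_rng(seed)
    x = np.empty((n_tracks, n_steps))
    x[:, 0] = mean
    for t in range(1, n_steps):
        x[:, t] = (
            x[:, t - 1]
            + reversion * (mean - x[:, t - 1])
            + rng.standard_normal(n_tracks) * noise_sd
        )
    return x


# ---------------------------------------------------------------------------
# Lineage simulation
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class _Focus:
    focus_id: int
    x: float            # left-anchored position, um
    regime: str         # "near" | "far"
    stream: np.ndarray  # precomputed fGn increments for this focus
    step: int = 0

    def next_fgn(self) -> float:
        dx = float(self.stream[min(self.step, len(self.stream) - 1)])
        self.step += 1
        return dx


@dataclass
class _Cell:
    cell_id: int
    parent_id: int | None
    birth_time: float
    birth_length: float
    new_pole_end: str   # "left" | "right"
    generation: int
    foci: list = field(default_factory=list)
    has_split: bool = False

    def length(self, t: float, rate: float) -> float:
        return self.birth_length * np.exp(rate * (t - self.birth_time))


def _from_new_pole(x_left: float, length: float, new_pole_end: str) -> float:
    return x_left if new_pole_end == "left" else length - x_left

_MAX_FRAMES = 400


def simulate_lineage(
    params: SimParams, n_generations: int
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate an asymmetrically dividing lineage for ``n_generations`` rounds.

    Returns the per-frame cell table and the full :class:`GroundTruth`.
    Cells elongate exponentially, divide at ``division_length`` at a plane
    placed ``division_asymmetry`` (jittered) of the way from the new pole,
    and each daughter's new pole is the division-plane end.  The single ParB
    focus splits mid-cycle into a near-regime child (fGn motion, stays by
    the ParA maximum) and a far-regime child (directed toward the old pole
    once beyond ``regime_switch_distance`` from the maximum).  The ParA
    maximum sits ``parA_peak_frac`` of the length from the new pole and
    relocates next to the division plane on the final pre-division frame.
    """
    if n_generations < 1:
        raise ValueError("n_generations must be >= 1")
    p = params
    rng = np.random.default_rng(p.seed)
    dt = p.frame_interval
    # one Cholesky factor shared by every focus stream
    chol = _fgn_cholesky(_MAX_FRAMES, p.near_regime_hurst, p.step_scale_um)

    def new_stream() -> np.ndarray:
        return chol @ rng.standard_normal(_MAX_FRAMES)

    next_cell, next_focus = [1], [1]

    def make_cell(parent, t, L0, pole, gen, foci):
        c = _Cell(next_cell[0], parent, t, L0, pole, gen, foci)
        next_cell[0] += 1
        return c

    def make_focus(x, regime):
        f = _Focus(next_focus[0], x, regime, new_stream())
        next_focus[0] += 1
        return f

    root = make_cell(None, 0.0, p.initial_length_um, "left", 0, [])
    root.foci = [make_focus(0.5 * p.initial_length_um, "near")]
    live = [root]

    rows_cells, rows_foci, rows_para = [], [], []
    rows_div, rows_split = [], []
    # frames after the last division during which terminal cells stay observed
    tail_left = 10

    for frame in range(_MAX_FRAMES):
        t = frame * dt
        if not live:
            break
        can_divide = any(c.generation < n_generations for c in live)
        if not can_divide:
            tail_left -= 1
            if tail_left < 0:
                break
        born: list[_Cell] = []
        dead: list[_Cell] = []
        for cell in live:
            L = cell.length(t, p.elongation_rate)
            dividing = L >= p.division_length and cell.generation < n_generations

            # ParA maximum (left-anchored)
            if dividing:
                q = float(np.clip(
                    p.division_asymmetry + rng.normal(0.0, p.division_jitter_sd),
                    0.5, 0.95,
                ))
                plane_np = q * L  # plane, measured from the new pole
                plane_left = plane_np if cell.new_pole_end == "left" else L - plane_np
                # ParA relocates beside the incipient septum, on the
                # new-pole (larger-daughter) side of the plane
                off = min(0.15, 0.45 * plane_np)
                a_np = plane_np - off
            else:
                a_np = p.parA_peak_frac * L
            a_left = a_np if cell.new_pole_end == "left" else L - a_np

            # focus split: one focus becomes a near + a far sibling
            if (not cell.has_split and len(cell.foci) == 1
                    and L >= p.split_length_frac * p.division_length):
                parent_focus = cell.foci[0]
                x0 = parent_focus.x
                d_near = make_focus(x0, "near")
                d_far = make_focus(x0, "far")
                # the near child steps toward the ParA max, the far child away
                sign = 1.0 if a_left > x0 else -1.0
                d_near.x = float(np.clip(x0 + sign * p.split_offset_um, 0.05, L - 0.05))
                d_far.x = float(np.clip(x0 - sign * p.split_offset_um, 0.05, L - 0.05))
                cell.foci = [d_near, d_far]
                cell.has_split = True
                rows_split.append({
                    "frame": frame, "cell_id": cell.cell_id,
                    "parent_focus_id": parent_focus.focus_id,
                    "child_near_id": d_near.focus_id,
                    "child_far_id": d_far.focus_id,
                })

            rows_cells.append({
                "frame": frame, "time_h": t, "cell_id": cell.cell_id,
                "parent_id": cell.parent_id, "length_um": L,
                "new_pole_end": cell.new_pole_end,
            })
            rows_para.append({
                "frame": frame, "cell_id": cell.cell_id,
                "x_left_um": a_left,
                "position_um": _from_new_pole(a_left, L, cell.new_pole_end),
            })
            for f in cell.foci:
                rows_foci.append({
                    "frame": frame, "cell_id": cell.cell_id,
                    "focus_id": f.focus_id, "x_left_um": f.x,
                    "position_um": _from_new_pole(f.x, L, cell.new_pole_end),
                })

            if dividing:
                # daughters appear next frame; new pole faces the plane
                d_new_side_len, d_old_side_len = plane_np, L - plane_np
                if cell.new_pole_end == "left":
                    seg_new = (0.0, plane_left)       # contains parent's new pole
                    seg_old = (plane_left, L)
                    pole_new_side, pole_old_side = "right", "left"
                else:
                    seg_new = (plane_left, L)
                    seg_old = (0.0, plane_left)
                    pole_new_side, pole_old_side = "left", "right"
                foci_new = [f for f in cell.foci if seg_new[0] <= f.x < seg_new[1]]
                foci_old = [f for f in cell.foci if f not in foci_new]
                for f in foci_new + foci_old:
                    f.regime = "near"

                def shift(foci, seg):
                    for f in foci:
                        f.x = float(np.clip(f.x - seg[0], 0.05, seg[1] - seg[0] - 0.05))
                    return foci

                da = make_cell(cell.cell_id, t + dt, d_new_side_len, pole_new_side,
                               cell.generation + 1, shift(foci_new, seg_new))
                db = make_cell(cell.cell_id, t + dt, d_old_side_len, pole_old_side,
                               cell.generation + 1, shift(foci_old, seg_old))
                larger = da if d_new_side_len >= d_old_side_len else db
                rows_div.append({
                    "frame": frame, "parent_id": cell.cell_id,
                    "daughter_new_side": da.cell_id, "daughter_old_side": db.cell_id,
                    "plane_left_um": plane_left,
                    "larger_daughter": larger.cell_id,
                    # ParA max sits on the new-pole side of the plane
                    "max_inheritor": da.cell_id,
                })
                born.extend([da, db])
                dead.append(cell)
            else:
                # propagate foci to the next frame
                L_next = cell.length(t + dt, p.elongation_rate)
                stretch = L_next / L
                a_next = a_left * stretch
                for f in cell.foci:
                    x = f.x * stretch
                    # sub-diffusive inside the ParA zone; directed beyond it
                    # (far sibling heads to the old pole, everything else is
                    # recaptured toward the ParA maximum)
                    if abs(x - a_next) > p.regime_switch_distance:
                        if f.regime == "far":
                            direction = 1.0 if cell.new_pole_end == "left" else -1.0
                        else:
                            direction = 1.0 if a_next > x else -1.0
                        x += direction * p.far_regime_speed * dt
                    else:
                        x += f.next_fgn()
                    f.x = float(np.clip(x, 0.05, L_next - 0.05))
        for c in dead:
            live.remove(c)
        live.extend(born)

    cells = pd.DataFrame(rows_cells)
    truth = GroundTruth(
        cells=cells,
        foci=pd.DataFrame(rows_foci),
        para_max=pd.DataFrame(rows_para),
        divisions=pd.DataFrame(
            rows_div, columns=["frame", "parent_id", "daughter_new_side",
                               "daughter_old_side", "plane_left_um",
                               "larger_daughter", "max_inheritor"]),
        splits=pd.DataFrame(
            rows_split, columns=["frame", "cell_id", "parent_focus_id",
                                 "child_near_id", "child_far_id"]),
    )
    return cells, truth


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def render_profiles(truth: GroundTruth, params: SimParams) -> pd.DataFrame:
    """Render noisy two-channel axial profiles for every cell-frame.

    ParB channel: baseline + Gaussian spots (sd ``spot_sigma``) at the true
    focus positions; ParA channel: baseline + Gaussian bump (sd
    ``parA_peak_width``) at the true maximum; both plus i.i.d. Gaussian
    noise, clipped at zero.  Pixel i samples axial position i * pixel_size
    from the cell's left end (grid spans [0, L]).  Cells shorter than 3
    pixels are dropped.  Long-format columns: cell_id, frame, pixel_index,
    parA_intensity, parB_intensity.
    """
    if truth.cells.empty:
        raise ValueError("ground truth contains no frames")
    p = params
    rng = np.random.default_rng(p.seed + 7)  # rendering noise stream
    foci_by = {
        k: g["x_left_um"].to_numpy()
        for k, g in truth.foci.groupby(["cell_id", "frame"])
    }
    para_by = {
        (r.cell_id, r.frame): r.x_left_um
        for r in truth.para_max.itertuples()
    }
    chunks = []
    for row in truth.cells.itertuples():
        n_px = int(np.floor(row.length_um / p.pixel_size)) + 1
        if n_px < 3:
            continue
        x = np.arange(n_px) * p.pixel_size
        parB = np.full(n_px, p.parB_baseline, dtype=float)
        for x0 in foci_by.get((row.cell_id, row.frame), ()):
            parB += p.parB_amplitude * np.exp(-0.5 * ((x - x0) / p.spot_sigma) ** 2)
        a0 = para_by[(row.cell_id, row.frame)]
        parA = p.parA_baseline + p.parA_amplitude * np.exp(
            -0.5 * ((x - a0) / p.parA_peak_width) ** 2
        )
        if p.noise_sd > 0:
            parB = parB + rng.normal(0.0, p.noise_sd, n_px)
            parA = parA + rng.normal(0.0, p.noise_sd, n_px)
        chunks.append(pd.DataFrame({
            "cell_id": row.cell_id, "frame": row.frame,
            "pixel_index": np.arange(n_px),
            "parA_intensity": np.clip(parA, 0.0, None),
            "parB_intensity": np.clip(parB, 0.0, None),
        }))
    cols = ["cell_id", "frame", "pixel_index", "parA_intensity", "parB_intensity"]
    if not chunks:
        return pd.DataFrame(columns=cols)
    return pd.concat(chunks, ignore_index=True)


def write_dataset(
    outdir: str | Path, cells: pd.DataFrame, profiles: pd.DataFrame, truth: GroundTruth
) -> dict[str, Path]:
    """Write cells.csv, profiles.csv and ground_truth.json under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "cells": outdir / "cells.csv",
        "profiles": outdir / "profiles.csv",
        "truth": outdir / "ground_truth.json",
    }
    cells.to_csv(paths["cells"], index=False)
    profiles.to_csv(paths["profiles"], index=False)
    truth.to_json(paths["truth"])
    return paths
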