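"""Diffusion-regime and directionality analysis of ParB focus tracks.

For every tracked focus the unsigned axial distance to the ParA intensity
maximum is followed over time.  Displacements over all time-window
combinations are pooled into distance bins chosen by each track's *initial*
distance from the maximum, giving binned mean-squared-displacement (MSD)
curves with t-interval 95% CIs.  Each bin's curve is fitted to the
anomalous-diffusion power law

    <dx^2> = 2 D (dt)^beta

by ordinary least squares on log-log axes; the exponent classifies the
motion (beta < 1 sub-diffusive, = 1 free diffusion, > 1 active transport).
Separately, each track's drift relative to the maximum (OLS slope of the
distance against time) classifies it as moving toward, with, or away from
the ParA maximum against a fixed speed threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tracking import FocusTrack

DEFAULT_BIN_EDGES_UM = (0.0, 1.5, 3.0, 4.5)
VELOCITY_THRESHOLD_UM_H = 0.15


@dataclass
class DistanceSeries:
    """Per-frame unsigned distance of one focus track to the ParA maximum."""

    track_id: int
    frames: np.ndarray
    times: np.ndarray       # h
    distances: np.ndarray   # um, >= 0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.times = np.asarray(self.times, dtype=float)
        self.distances = np.asarray(self.distances, dtype=float)
        if np.any(self.distances < 0):
            raise ValueError("distances must be non-negative")

    @property
    def initial_distance(self) -> float:
        return float(self.distances[0])

    def __len__(self) -> int:
        return int(self.distances.size)


@dataclass
class PowerLawFit:
    D: float                # um^2 / h^beta
    beta: float
    se_D: float
    se_beta: float
    n_points: int
    regime: str             # "subdiffusive" | "free" | "active"


@dataclass
class VelocityClass:
    track_id: int
    slope_um_per_h: float
    slope_se: float
    label: str              # "toward" | "with" | "away"


def distance_to_para_max(
    track: FocusTrack,
    maxima: pd.DataFrame,
    frame_interval_h: float,
) -> DistanceSeries | None:
    """Unsigned distance between a track's foci and the per-frame ParA maximum.

    ``maxima`` columns: cell_id, frame, position_um (NaN when the maximum
    is undefined; those frames are skipped).  Returns None when no frame
    overlaps.
    """
    lut = {(int(r.cell_id), int(r.frame)): r.position_um for r in maxima.itertuples()}
    frames, dists = [], []
    for f in track.foci:
        m = lut.get((f.cell_id, f.frame))
        if m is None or math.isnan(m):
            continue
        frames.append(f.frame)
        dists.append(abs(f.position_um - m))
    if not frames:
        return None
    frames = np.asarray(frames)
    return DistanceSeries(
        track_id=track.track_id,
        frames=frames,
        times=frames * frame_interval_h,
        distances=np.asarray(dists),
    )


def msd_binned(
    series: list[DistanceSeries],
    bin_edges_um: tuple[float, ...] = DEFAULT_BIN_EDGES_UM,
    frame_interval_h: float = 0.25,
    max_lag: int | None = None,
) -> pd.DataFrame:
    """Binned MSD of distance changes over all time-window combinations.

    Each series contributes the squared change in distance
    ``(d(t+dt) - d(t))^2`` for *every* ordered pair of its time points, all
    to the single bin selected by its initial distance (half-open bins
    ``[lo, hi)``); series starting beyond the last edge are discarded as
    too sparse to average.  Per bin and lag the mean, Student-t 95% CI of
    the mean and the pair count are reported.  ``max_lag`` defaults to half
    the longest series length, so single-pair tails do not dominate fits.

    Returns a DataFrame with columns bin_lo, bin_hi, dt_h, msd_um2,
    ci_low, ci_high, n_pairs.
    """
    edges = list(bin_edges_um)
    usable = [s for s in series if len(s) >= 2 and s.initial_distance < edges[-1]]
    if max_lag is None:
        longest = max((len(s) for s in usable), default=2)
        max_lag = max(longest // 2, 1)
    pools: dict[tuple[int, int], list[np.ndarray]] = {}
    for s in usable:
        b = int(np.searchsorted(edges, s.initial_distance, side="right") - 1)
        b = max(b, 0)
        d = s.distances
        fr = s.frames
        for i in range(len(d) - 1):
            lags = fr[i + 1:] - fr[i]
            keep = lags <= max_lag
            if not np.any(keep):
                continue
            dx2 = (d[i + 1:][keep] - d[i]) ** 2
            for lag, v in zip(lags[keep], dx2):
                pools.setdefault((b, int(lag)), []).append(v)
    rows = []
    for b in range(len(edges) - 1):
        for lag in range(1, max_lag + 1):
            vals = np.asarray(pools.get((b, lag), []), dtype=float)
            n = vals.size
            if n == 0:
                rows.append({"bin_lo": edges[b], "bin_hi": edges[b + 1],
                             "dt_h": lag * frame_interval_h, "msd_um2": math.nan,
                             "ci_low": math.nan, "ci_high": math.nan, "n_pairs": 0})
                continue
            mean = float(vals.mean())
            if n > 1:
                half = float(stats.t.ppf(0.975, n - 1) * vals.std(ddof=1) / math.sqrt(n))
            else:
                half = math.nan
            rows.append({"bin_lo": edges[b], "bin_hi": edges[b + 1],
                         "dt_h": lag * frame_interval_h, "msd_um2": mean,
                         "ci_low": mean - half, "ci_high": mean + half,
                         "n_pairs": n})
    return pd.DataFrame(rows)


def fit_powerlaw(
    dt_h: np.ndarray, msd_um2: np.ndarray, regime_tol: float = 0.1
) -> PowerLawFit | None:
    """OLS fit of ln<dx^2> = ln(2D) + beta ln(dt).

    Non-positive means are excluded (their logarithm is undefined); fewer
    than 3 surviving points make the fit undefined (None).  ``regime_tol``
    is the half-width of the band around beta = 1 labelled free diffusion.
    """
    dt = np.asarray(dt_h, dtype=float)
    msd = np.asarray(msd_um2, dtype=float)
    ok = np.isfinite(msd) & (msd > 0) & np.isfinite(dt) & (dt > 0)
    dt, msd = dt[ok], msd[ok]
    if np.unique(dt).size < 3:
        return None
    fit = stats.linregress(np.log(dt), np.log(msd))
    beta = float(fit.slope)
    D = float(math.exp(fit.intercept) / 2.0)
    se_beta = float(fit.stderr)
    se_D = float(D * fit.intercept_stderr)  # delta method on exp(intercept)/2
    if beta < 1 - regime_tol:
        regime = "subdiffusive"
    elif beta > 1 + regime_tol:
        regime = "active"
    else:
        regime = "free"
    return PowerLawFit(D=D, beta=beta, se_D=se_D, se_beta=se_beta,
                       n_points=int(dt.size), regime=regime)


def fit_msd_table(
    msd: pd.DataFrame, regime_tol: float = 0.1
) -> dict[tuple[float, float], PowerLawFit | None]:
    """Run :func:`fit_powerlaw` for every distance bin of an MSD table."""
    out = {}
    for (lo, hi), g in msd.groupby(["bin_lo", "bin_hi"], sort=True):
        out[(lo, hi)] = fit_powerlaw(
            g["dt_h"].to_numpy(), g["msd_um2"].to_numpy(), regime_tol
        )
    return out


def classify_velocity(
    series: DistanceSeries,
    threshold_um_h: float = VELOCITY_THRESHOLD_UM_H,
) -> VelocityClass | None:
    """Classify a track by the OLS slope of its ParA distance over time.

    Slope below -threshold: moving toward the maximum; above +threshold:
    away; otherwise travelling with it.  Needs at least 3 points.
    """
    if len(series) < 3:
        return None
    fit = stats.linregress(series.times, series.distances)
    slope = float(fit.slope)
    if slope < -threshold_um_h:
        label = "toward"
    elif slope > threshold_um_h:
        label = "away"
    else:
        label = "with"
    return VelocityClass(
        track_id=series.track_id, slope_um_per_h=slope,
        slope_se=float(fit.stderr), label=label,
    )


def summarize_directionality(classes: list[VelocityClass]) -> dict:
    """Counts and fractions per motion class, plus the toward-or-with share."""
    if not classes:
        raise ValueError("no classified tracks")
    counts = {"toward": 0, "with": 0, "away": 0}
    for c in classes:
        counts[c.label] += 1
    n = len(classes)
    fractions = {k: v / n for k, v in counts.items()}
    return {
        "n": n,
        "counts": counts,
        "fractions": fractions,
        "toward_or_with": (counts["toward"] + counts["with"]) / n,
    }


def series_from_positions(
    positions: np.ndarray, dt_h: float, start_track_id: int = 1
) -> list[DistanceSeries]:
    """Wrap an (n_tracks, n_steps) position array as distance series.

    Each trajectory is shifted by a per-track constant (its own minimum) so
    distances are non-negative; a constant shift leaves every displacement
    dx — and hence the MSD and fitted exponent — exactly unchanged.  Used
    to feed simulated motion classes through the same MSD/fit machinery as
    real tracks.
    """
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    out = []
    for i, row in enumerate(pos):
        frames = np.arange(row.size)
        out.append(DistanceSeries(
            track_id=start_track_id + i,
            frames=frames,
            times=frames * dt_h,
            distances=row - row.min(),
        ))
    return out
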