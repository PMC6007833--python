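"""Pipeline orchestration: smooth -> detect -> validate -> track -> analyse.

Each stage reads/writes plain CSV/JSON under an output directory, stamped
with the configuration hash and master seed, so a run is reproducible from
(inputs, config, seed) alone.  Per-profile validation noise is seeded from
a :class:`numpy.random.SeedSequence` spawned per (cell, frame), making
results independent of execution order.
"""

from __future__ import annotations

import json
import logging
import math
import time
from dataclasses import asdict
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import detection, dynamics, inheritance, lineage, profiles, synthetic, tracking
from .config import PipelineConfig

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Stamped I/O helpers
# ---------------------------------------------------------------------------

def _write_csv(df: pd.DataFrame, path: Path, config: PipelineConfig) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config.config_hash()} seed={config.seed}\n")
        df.to_csv(fh, index=False)
    return path

def _write_json(obj, path: Path, config: PipelineConfig) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"config_hash": config.config_hash(), "seed": config.seed, **obj}
    path.write_text(json.dumps(payload, indent=1, default=float))
    return path

def read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def _profile_seed(master: int, cell_id: int, frame: int) -> int:
    ss = np.random.SeedSequence([master, int(cell_id), int(frame)])
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(
    config: PipelineConfig,
    outdir: str | Path,
    n_generations: int = 3,
    sim_overrides: dict | None = None,
) -> dict[str, Path]:
    """Generate a synthetic movie and write cells.csv / profiles.csv / truth."""
    kwargs = dict(
        pixel_size=config.pixel_size_um,
        frame_interval=config.frame_interval_h,
        seed=config.seed,
    )
    kwargs.update(sim_overrides or {})
    params = synthetic.SimParams(**kwargs)
    cells, truth = synthetic.simulate_lineage(params, n_generations)
    profs = synthetic.render_profiles(truth, params)
    return synthetic.write_dataset(outdir, cells, profs, truth)


def stage_detect(
    cells: pd.DataFrame,
    profile_table: pd.DataFrame,
    config: PipelineConfig,
    outdir: str | Path,
) -> dict[str, Path]:
    """Smooth both channels; detect+validate ParB foci; locate ParA maxima."""
    outdir = Path(outdir)
    cfg = detection.DetectionConfig(
        min_separation_px=config.peak_min_separation_px,
        threshold_rel=config.peak_threshold_rel,
        n_trials=config.noise_trials,
        retain_min=config.noise_retain_min,
        noise_sigma_factor=config.noise_sigma_factor,
        resmooth_sigma_px=config.resmooth_sigma_px,
        match_radius_px=config.match_radius_px,
    )
    parB = profiles.profiles_from_table(profile_table, cells, config.pixel_size_um, "parB")
    rows = []
    for p in parB:
        sm = profiles.smooth_profile(p, config.smoothing_sigma_px)
        cands = detection.detect_peaks(sm, cfg)
        kept = detection.validate_peaks(
            sm, cands, cfg, seed=_profile_seed(config.seed, p.cell_id, p.frame)
        )
        for f in kept:
            rows.append({
                "cell_id": f.cell_id, "frame": f.frame,
                "position_px": f.position_px, "position_um": f.position_um,
                "intensity": f.intensity, "validation_count": f.validation_count,
            })
    foci = pd.DataFrame(rows, columns=["cell_id", "frame", "position_px",
                                       "position_um", "intensity", "validation_count"])
    parA = profiles.profiles_from_table(profile_table, cells, config.pixel_size_um, "parA")
    maxima = profiles.para_maxima_table(parA, config.smoothing_sigma_px)
    return {
        "foci": _write_csv(foci, outdir / "foci.csv", config),
        "para_maxima": _write_csv(maxima, outdir / "para_maxima.csv", config),
    }


def _foci_from_table(df: pd.DataFrame) -> list[detection.Focus]:
    return [
        detection.Focus(
            cell_id=int(r.cell_id), frame=int(r.frame),
            position_px=int(r.position_px), position_um=float(r.position_um),
            intensity=float(r.intensity),
            validation_count=int(r.validation_count),
        )
        for r in df.itertuples()
    ]


def stage_track(
    cells: pd.DataFrame,
    foci: pd.DataFrame,
    config: PipelineConfig,
    outdir: str | Path,
    override_file: str | Path | None = None,
) -> dict[str, Path]:
    """Link validated foci into tracks and assign split events."""
    outdir = Path(outdir)
    tree = lineage.build_lineage(cells)
    tracks = tracking.link_foci(
        _foci_from_table(foci), tree,
        max_step_px=config.link_max_px, pixel_size=config.pixel_size_um,
    )
    tracks = tracking.assign_splits(
        tracks, tree, split_radius_px=config.split_radius_px,
        pixel_size=config.pixel_size_um,
    )
    tracks = tracking.apply_overrides(tracks, override_file)
    return {"tracks": _write_csv(tracking.tracks_to_table(tracks),
                                 outdir / "tracks.csv", config)}


def _tracks_from_table(df: pd.DataFrame) -> list[tracking.FocusTrack]:
    out = []
    for tid, g in df.groupby("track_id", sort=True):
        g = g.sort_values("frame")
        foci = [
            detection.Focus(cell_id=int(r.cell_id), frame=int(r.frame),
                            position_px=-1, position_um=float(r.position_um),
                            intensity=math.nan, validation_count=-1)
            for r in g.itertuples()
        ]
        pid = g["parent_track_id"].iloc[0]
        out.append(tracking.FocusTrack(
            track_id=int(tid), foci=foci,
            parent_track_id=None if pd.isna(pid) else int(pid),
        ))
    return out


def _distance_series(
    tracks_df: pd.DataFrame, maxima: pd.DataFrame, config: PipelineConfig
) -> list[dynamics.DistanceSeries]:
    series = []
    for tr in _tracks_from_table(tracks_df):
        s = dynamics.distance_to_para_max(tr, maxima, config.frame_interval_h)
        if s is not None and len(s) >= 2:
            series.append(s)
    return series


def stage_msd(
    tracks_df: pd.DataFrame,
    maxima: pd.DataFrame,
    config: PipelineConfig,
    outdir: str | Path,
) -> dict[str, Path]:
    """Binned MSD curves and per-bin power-law fits."""
    outdir = Path(outdir)
    series = _distance_series(tracks_df, maxima, config)
    msd = dynamics.msd_binned(
        series, tuple(config.msd_bin_edges_um), config.frame_interval_h
    )
    fits = dynamics.fit_msd_table(msd)
    fit_rows = {
        f"bin_{lo}_{hi}": (None if f is None else asdict(f))
        for (lo, hi), f in fits.items()
    }
    return {
        "msd": _write_csv(msd, outdir / "msd.csv", config),
        "fits": _write_json({"fits": fit_rows}, outdir / "msd_fits.json", config),
    }


def stage_velocity(
    tracks_df: pd.DataFrame,
    maxima: pd.DataFrame,
    config: PipelineConfig,
    outdir: str | Path,
) -> dict[str, Path]:
    """Per-track drift relative to the ParA maximum and its classification."""
    outdir = Path(outdir)
    series = _distance_series(tracks_df, maxima, config)
    classes = [
        c for s in series
        if (c := dynamics.classify_velocity(s, config.velocity_threshold_um_h))
    ]
    vel = pd.DataFrame(
        [{"track_id": c.track_id, "slope_um_per_h": c.slope_um_per_h,
          "slope_se": c.slope_se, "class": c.label} for c in classes],
        columns=["track_id", "slope_um_per_h", "slope_se", "class"],
    )
    summary = dynamics.summarize_directionality(classes) if classes else {
        "n": 0, "counts": {}, "fractions": {}, "toward_or_with": math.nan}
    return {
        "velocity": _write_csv(vel, outdir / "velocity.csv", config),
        "directionality": _write_json(summary, outdir / "directionality.json", config),
    }


def stage_inherit(
    cells: pd.DataFrame,
    profile_table: pd.DataFrame,
    config: PipelineConfig,
    outdir: str | Path,
) -> dict[str, Path]:
    """Sibling ParA attributes, inheritance null prediction and group tests."""
    outdir = Path(outdir)
    tree = lineage.build_lineage(cells)
    parA = profiles.profiles_from_table(profile_table, cells, config.pixel_size_um, "parA")
    first = {}
    last = {}
    for p in parA:
        if p.cell_id not in first or p.frame < first[p.cell_id].frame:
            first[p.cell_id] = p
        if p.cell_id not in last or p.frame > last[p.cell_id].frame:
            last[p.cell_id] = p
    pairs = []
    for parent_id in tree.children:
        if parent_id not in last:
            continue
        pair = inheritance.sibling_attributes(
            tree, parent_id,
            birth_profiles=first, parent_last_profile=last[parent_id],
            smoothing_sigma_px=config.smoothing_sigma_px,
        )
        if pair is not None:
            pairs.append(pair)
    rows = []
    for p in pairs:
        for d in (p.daughter_a, p.daughter_b):
            rows.append({
                "parent_id": p.parent_id, "daughter_id": d,
                "total_parA": p.total_parA[d], "max_parA": p.max_parA[d],
                "birth_length_um": p.birth_length[d],
                "birth_area_um2": p.birth_area[d],
                "growth_rate": p.growth_rate[d],
                "is_high_total": d == p.high_total_inheritor,
                "is_max_inheritor": d == p.max_inheritor,
                "is_larger": d == p.larger,
                "max_tie": p.max_tie,
            })
    pairs_df = pd.DataFrame(rows, columns=[
        "parent_id", "daughter_id", "total_parA", "max_parA", "birth_length_um",
        "birth_area_um2", "growth_rate", "is_high_total", "is_max_inheritor",
        "is_larger", "max_tie"])
    out = {"pairs": _write_csv(pairs_df, outdir / "sibling_pairs.csv", config)}
    if pairs:
        pred = inheritance.predict_random_inheritance(pairs)
        out["prediction"] = _write_json(asdict(pred),
                                        outdir / "inheritance_prediction.json", config)
    if len(pairs) >= 6:
        tests = {
            f"{grouping}_{attribute}": inheritance.compare_inheritor_groups(
                pairs, attribute, grouping)
            for grouping in ("total", "max", "size")
            for attribute in ("area", "growth_rate")
        }
        out["group_tests"] = _write_json({"tests": tests},
                                         outdir / "inheritance_tests.json", config)
    return out


def stage_sizes(
    size_table: pd.DataFrame, config: PipelineConfig, outdir: str | Path
) -> dict[str, Path]:
    """Between-strain cell-size comparison (Kruskal-Wallis + Dunn letters).

    ``size_table`` columns: strain, length_um.
    """
    outdir = Path(outdir)
    groups = {
        str(s): g["length_um"].to_numpy()
        for s, g in size_table.groupby("strain")
    }
    res = inheritance.compare_size_distributions(groups)
    payload = {k: v for k, v in res.items() if k != "dunn"}
    payload["dunn"] = res["dunn"].to_dict(orient="records")
    return {"sizes": _write_json(payload, outdir / "size_comparison.json", config)}


# ---------------------------------------------------------------------------
# Kymograph rendering
# ---------------------------------------------------------------------------

def build_kymograph_array(heatmap: profiles.ParaHeatmap) -> np.ndarray:
    """(n_pixels, n_frames) image of one cell's normalised ParA heatmap.

    Row 0 is the new pole; frames shorter than the final length are
    top-padded with NaN (the cell grows upward in the rendering).
    """
    n_px = max(p.size for p in heatmap.profiles)
    img = np.full((n_px, len(heatmap.profiles)), np.nan)
    for j, prof in enumerate(heatmap.profiles):
        img[: prof.size, j] = prof
    return img


def render_kymograph(
    heatmap: profiles.ParaHeatmap,
    tracks_df: pd.DataFrame | None,
    path: str | Path,
    frame_interval_h: float = 0.25,
) -> Path:
    """Save a kymograph panel: ParA gradient (black=min, white=max) over
    time with ParB focus tracks overlaid, new pole at the bottom."""
    img = build_kymograph_array(heatmap)
    fig, ax = plt.subplots(figsize=(6, 4))
    extent = (
        heatmap.frames[0] * frame_interval_h,
        (heatmap.frames[-1] + 1) * frame_interval_h,
        0.0,
        img.shape[0] * heatmap.pixel_size,
    )
    cmap = plt.get_cmap("gray").copy()
    cmap.set_bad("0.85")  # outside-the-cell padding, distinct from signal
    ax.imshow(img, cmap=cmap, origin="lower", aspect="auto",
              extent=extent, vmin=0, vmax=1)
    if tracks_df is not None and not tracks_df.empty:
        sel = tracks_df[tracks_df["cell_id"] == heatmap.cell_id]
        for tid, g in sel.groupby("track_id"):
            g = g.sort_values("frame")
            ax.plot((g["frame"] + 0.5) * frame_interval_h, g["position_um"],
                    color="0.7", marker="o", ms=3, mfc="black", lw=1.2)
    ax.set_xlabel("time (h)")
    ax.set_ylabel("position from new pole (um)")
    ax.set_title(f"cell {heatmap.cell_id}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def stage_report(
    cells: pd.DataFrame,
    profile_table: pd.DataFrame,
    tracks_df: pd.DataFrame | None,
    config: PipelineConfig,
    outdir: str | Path,
    max_cells: int = 6,
) -> list[Path]:
    """Render per-cell kymographs for the first ``max_cells`` cells."""
    outdir = Path(outdir)
    parA = profiles.profiles_from_table(profile_table, cells, config.pixel_size_um, "parA")
    by_cell: dict[int, list] = {}
    for p in parA:
        by_cell.setdefault(p.cell_id, []).append(p)
    out = []
    for cid in sorted(by_cell)[:max_cells]:
        smoothed = [profiles.smooth_profile(p, config.smoothing_sigma_px)
                    for p in by_cell[cid]]
        hm = profiles.normalize_para_heatmap(smoothed)
        out.append(render_kymograph(hm, tracks_df, outdir / f"kymograph_cell{cid}.png",
                                    config.frame_interval_h))
    return out


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def run_pipeline(
    config: PipelineConfig,
    cells_csv: str | Path,
    profiles_csv: str | Path,
    outdir: str | Path,
    override_file: str | Path | None = None,
    render: bool = False,
) -> dict[str, Path]:
    """Execute detect -> track -> (msd, velocity, inheritance) in order.

    Every stage logs its wall time; outputs land under ``outdir`` stamped
    with the config hash and seed.  A stage failure propagates with the
    stage name attached; earlier outputs are left in place.
    """
    outdir = Path(outdir)
    cells = read_csv(cells_csv)
    prof = read_csv(profiles_csv)
    outputs: dict[str, Path] = {}
    stages = [
        ("detect", lambda: stage_detect(cells, prof, config, outdir)),
        ("track", lambda: stage_track(cells, read_csv(outputs["foci"]), config,
                                      outdir, override_file)),
        ("msd", lambda: stage_msd(read_csv(outputs["tracks"]),
                                  read_csv(outputs["para_maxima"]), config, outdir)),
        ("velocity", lambda: stage_velocity(read_csv(outputs["tracks"]),
                                            read_csv(outputs["para_maxima"]),
                                            config, outdir)),
        ("inherit", lambda: stage_inherit(cells, prof, config, outdir)),
    ]
    for name, fn in stages:
        t0 = time.perf_counter()
        try:
            outputs.update(fn())
        except Exception as exc:  # noqa: BLE001 - annotate stage and re-raise
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        logger.info("stage %-8s %.2fs", name, time.perf_counter() - t0)
    if render:
        tracks_df = read_csv(outputs["tracks"])
        stage_report(cells, prof, tracks_df, config, outdir / "figures")
    return outputs
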