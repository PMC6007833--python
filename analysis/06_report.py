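#!/usr/bin/env python
"""Render kymograph panels and the per-bin MSD figure.

Produces Fig-style panels: per-cell grayscale ParA heatmaps over time
(black = lifetime minimum, white = lifetime maximum, new pole at the
bottom) with ParB focus tracks overlaid, plus log-log MSD curves with
their power-law fits.
"""

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from parabtrack.config import PipelineConfig
from parabtrack import pipeline

DATA = "results/data"
OUT = "results/analysis"
FIG = "results/figures"


def msd_figure(cfg) -> str:
    msd = pipeline.read_csv(f"{OUT}/msd.csv")
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5), sharey=True)
    for ax, (keys, g) in zip(axes, msd.groupby(["bin_lo", "bin_hi"], sort=True)):
        g = g[g.n_pairs > 0]
        ax.errorbar(g.dt_h, g.msd_um2,
                    yerr=[g.msd_um2 - g.ci_low, g.ci_high - g.msd_um2],
                    fmt="o", ms=3, lw=1)
        ax.set_xscale("log")
        ax.set_yscale("log")
        ax.set_title(f"initial distance {keys[0]}-{keys[1]} um")
        ax.set_xlabel("dt (h)")
    axes[0].set_ylabel("MSD (um^2)")
    path = f"{FIG}/msd_bins.png"
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def main() -> None:
    cfg = PipelineConfig(seed=1)
    cells = pipeline.read_csv(f"{DATA}/cells.csv")
    profs = pipeline.read_csv(f"{DATA}/profiles.csv")
    tracks = pipeline.read_csv(f"{OUT}/tracks.csv")
    panels = pipeline.stage_report(cells, profs, tracks, cfg, FIG, max_cells=4)
    for p in panels:
        print(f"  wrote {p}")
    print(f"  wrote {msd_figure(cfg)}")


if __name__ == "__main__":
    main()
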