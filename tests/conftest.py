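"""Shared fixtures: one synthetic movie and one full pipeline run per session."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from parabtrack import pipeline, synthetic
from parabtrack.config import PipelineConfig


@pytest.fixture(scope="session")
def sim_params() -> synthetic.SimParams:
    return synthetic.SimParams(seed=1)


@pytest.fixture(scope="session")
def sim_movie(sim_params):
    """Three-generation synthetic movie: (cells, truth, profiles)."""
    cells, truth = synthetic.simulate_lineage(sim_params, n_generations=3)
    profs = synthetic.render_profiles(truth, sim_params)
    return cells, truth, profs


@pytest.fixture(scope="session")
def pipeline_run(sim_movie, tmp_path_factory):
    """Full pipeline outputs on the default synthetic movie (seed 1)."""
    cells, truth, profs = sim_movie
    outdir = tmp_path_factory.mktemp("pipeline")
    cells.to_csv(outdir / "cells.csv", index=False)
    profs.to_csv(outdir / "profiles.csv", index=False)
    cfg = PipelineConfig(seed=1)
    outputs = pipeline.run_pipeline(
        cfg, outdir / "cells.csv", outdir / "profiles.csv", outdir / "out"
    )
    loaded = {k: (pipeline.read_csv(v) if str(v).endswith(".csv") else v)
              for k, v in outputs.items()}
    return {"config": cfg, "cells": cells, "truth": truth, "profiles": profs,
            "outputs": outputs, "tables": loaded, "outdir": outdir}


def match_true_focus(truth_foci: pd.DataFrame):
    """Closure mapping a detected (cell, frame, position) to a true focus id."""
    lut = {
        (int(c), int(f)): (g["position_um"].to_numpy(), g["focus_id"].to_numpy())
        for (c, f), g in truth_foci.groupby(["cell_id", "frame"])
    }

    def lookup(cell_id, frame, position_um, radius_um=0.2):
        pos, ids = lut.get((int(cell_id), int(frame)), (np.empty(0), None))
        if pos.size == 0:
            return None
        i = int(np.argmin(np.abs(pos - position_um)))
        return int(ids[i]) if abs(pos[i] - position_um) <= radius_um else None

    return lookup
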