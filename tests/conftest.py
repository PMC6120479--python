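"""Shared fixtures: small rendered fields and the two expensive
session-scoped simulation studies reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from poldep.depmatrix import normalize_to_controls
from poldep.design import GroundTruthEffect, planted_truth_table
from poldep.pipeline import full_scale_config, quantify_cells, validate_config
from poldep.synthgen import FieldParams, render_field

# study-condition geometry used by most small image tests: the coarser
# sampling of the full-scale preset keeps renders fast
FP = FieldParams(shape=(320, 320), pixel_size_xy=0.2)


@pytest.fixture(scope="session")
def small_null_field():
    """One default-noise field, 8 control + 8 deletion cells, no effect."""
    return render_field("Tea1", "for3", 8, 8, params=FP, seed=3,
                        field_id="null-0")


@pytest.fixture(scope="session")
def null_pool():
    """Large single-combination null study used for calibration tests:
    480 cells per arm over 60 fields, normalised. Subsampling this pool
    stands in for independent replicate studies."""
    cfg = validate_config(dict(
        markers=["Tea1"], deletions=["for3"], cells_per_arm=480,
        fields_per_combination=60, field_shape=(320, 320),
        pixel_size_xy=0.2, truth="null", seed=5))
    cells, counts = quantify_cells(cfg)
    norm = normalize_to_controls(cells)
    return {"cells": cells, "counts": counts, "normalized": norm}


@pytest.fixture(scope="session")
def full_scale_run():
    """Full-scale planted-truth study (81 combinations, 120 cells/arm).

    This is the expensive fixture of the suite (several minutes); the
    bookkeeping and parameter-recovery tests share one run."""
    cfg = full_scale_config(seed=1, truth="planted")
    cells, counts = quantify_cells(cfg)
    norm = normalize_to_controls(cells)
    truth = planted_truth_table(cfg.design(), seed=cfg.seed)
    return {"config": cfg, "cells": cells, "counts": counts,
            "normalized": norm, "truth": truth}


@pytest.fixture(scope="session")
def half_end_study():
    """One combination with a 0.5 multiplier planted on End1, ~100 cells
    per arm at default noise; returns (normalised records, truth)."""
    from poldep.depmatrix import normalize_to_controls
    from poldep.quantify import measurements_to_frame, quantify_field

    eff = GroundTruthEffect("Tea1", "tea2", mult_end1=0.5)
    frames = []
    for seed in range(13):
        stack = render_field("Tea1", "tea2", 8, 8, truth=eff, params=FP,
                             seed=200 + seed, field_id=f"h{seed}")
        fq = quantify_field(stack)
        frames.append(measurements_to_frame(fq.measurements))
    cells = pd.concat(frames, ignore_index=True)
    return normalize_to_controls(cells), eff


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
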