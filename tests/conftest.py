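import numpy as np
import pytest
from scipy.spatial import cKDTree

import calwave as cw


@pytest.fixture(scope="session")
def small_monolayer() -> cw.CellMap:
    """A 128x128 px jittered-grid monolayer (~36 cells)."""
    return cw.generate_monolayer(
        cw.MonolayerSpec(field_size=(128, 128), seed=11)
    )


@pytest.fixture(scope="session")
def quiet_movie(small_monolayer):
    """Noise-free movie of quiescent cells with 10% bleaching."""
    kin = cw.KineticsSpec(
        n_frames=200,
        noise_sd=0.0,
        baseline_cv=0.05,
        bleach_fraction=0.1,
        background=50.0,
        responsive_fraction_by_zone={"control": 0.0},
    )
    movie, events = cw.render_movie(small_monolayer, kin, seed=5)
    return movie, events, kin


def match_true_to_detected(
    true_cells: cw.CellMap, detected: cw.CellMap, tol_px: float = 2.0
):
    """Map true cell ids to detected ids by nearest center (within tol)."""
    d, idx = cKDTree(detected.centers).query(true_cells.centers)
    return {
        t: int(idx[t]) for t in range(true_cells.n_cells) if d[t] <= tol_px
    }
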