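import numpy as np
import pandas as pd
import pytest

import mfiquant as mq
from mfiquant.synthetic import DEFAULT_PANEL, ImageSpec, generate_cell_table


@pytest.fixture(scope="session")
def small_cohort():
    """Two-patient cohort with ground truth, shared across tests."""
    config = mq.nschl_quadrant_cohort(n_patients=2, n_cells=3000, seed=11)
    cells, truth = generate_cell_table(config)
    return config, cells, truth


@pytest.fixture(scope="session")
def analyzed_cohort(small_cohort):
    config, cells, truth = small_cohort
    result = mq.analyze_cell_table(
        cells, calibration_lineages=truth["lineage"], truth=truth, seed=5
    )
    return config, result


@pytest.fixture(scope="session")
def rendered_core():
    """A small noiseless rendered core with its ground-truth mask."""
    config = mq.nschl_quadrant_cohort(
        n_patients=1, n_cells=200, seed=3, noise_cv=0.0
    )
    cells, truth = generate_cell_table(config)
    core = cells[cells["patient_id"] == "NSCHL_01"]
    spec = ImageSpec(core_diameter_um=300.0, pixel_size_um=0.5)
    stack, mask, placed = mq.render_core_image(
        core, DEFAULT_PANEL, spec, np.random.default_rng(5)
    )
    return spec, stack, mask, placed.reset_index(drop=True), truth
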