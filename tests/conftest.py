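"""Shared fixtures: small grids and a session-scoped analyzed synthetic cohort."""

import numpy as np
import pytest

from pulvimap import CohortConfig, analyze_cohort, generate_subject
from pulvimap.synthetic_cohort import default_geometry
from pulvimap.volume_io import ROIMask

#: Significance gate used for desk-scale cohorts with 2 runs (df = 1); the
#: pipeline default of 0.001 presumes tens of runs (see docs/methods.md).
DESK_ALPHA = 0.05


@pytest.fixture(scope="session")
def small_geometry():
    return default_geometry(CohortConfig())


@pytest.fixture(scope="session")
def default_cohort():
    """Four-subject cohort at the standard study conditions, fixed seed."""
    cfg = CohortConfig(rng_seed=7)
    return cfg, [generate_subject(cfg, i) for i in range(cfg.n_subjects)]


@pytest.fixture(scope="session")
def default_result(default_cohort):
    """Full three-axis analysis of the default cohort."""
    _, subjects = default_cohort
    return analyze_cohort(subjects, alpha=DESK_ALPHA)


def line_mask(geometry, axis_index, lo, hi, fixed=None):
    """A 1-voxel-thick line of mask voxels along one array axis."""
    vox = np.zeros(geometry.dims, dtype=bool)
    sel = [geometry.dims[0] // 2, geometry.dims[1] // 2, geometry.dims[2] // 2]
    if fixed is not None:
        sel = list(fixed)
    idx = [slice(s, s + 1) for s in sel]
    idx[axis_index] = slice(lo, hi)
    vox[tuple(idx)] = True
    return ROIMask(geometry=geometry, voxels=vox, name="line")
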