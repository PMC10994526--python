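import numpy as np
import pytest

import eigenbrains as eb
from eigenbrains.simulate import SimConfig


@pytest.fixture(scope="session")
def small_grid():
    return eb.default_grid(dims=(12, 14, 12), voxel_mm=6.0)


@pytest.fixture(scope="session")
def small_config():
    """Reduced cohort for fast unit tests (same structure, fewer subjects)."""
    return SimConfig(seed=7, grid_dims=(12, 14, 12), group_sizes=(10, 6, 3, 6),
                     n_controls=20)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    images, clinical, truth, grid = eb.generate_cohort(small_config)
    return images, clinical, truth, grid


@pytest.fixture(scope="session")
def small_decomposition(small_cohort):
    """Normalized + smoothed small cohort carried through the SVD."""
    images, clinical, truth, grid = small_cohort
    proc = [eb.preprocess(im, grid, fwhm_mm=6.0) for im in images]
    mat = eb.build_matrix(proc, grid)
    dec = eb.svd_decompose(mat)
    return proc, mat, dec, truth, grid


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size cohort (117 patients + 117 controls) on the default grid."""
    cfg = SimConfig(seed=11)
    images, clinical, truth, grid = eb.generate_cohort(cfg)
    proc = [eb.preprocess(im, grid, fwhm_mm=6.0) for im in images]
    mat = eb.build_matrix(proc, grid)
    dec = eb.svd_decompose(mat)
    return {"config": cfg, "images": images, "clinical": clinical, "truth": truth,
            "grid": grid, "processed": proc, "matrix": mat, "decomposition": dec}


def scores_by_id(matrix_or_dec, clinical):
    """Reorder decomposition scores to clinical-table row order."""
    ids = list(matrix_or_dec.subject_ids)
    idx = [ids.index(s) for s in clinical["subject_id"]]
    return np.asarray(idx)
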