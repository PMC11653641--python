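"""Shared fixtures: small head models, banks and datasets built once per session."""

import numpy as np
import pytest
from scipy import sparse

from ictalesi import head_model as hm
from ictalesi import nmm, simulate


@pytest.fixture(scope="session")
def small_space():
    """60-region spherical source space."""
    return hm.build_spherical_source_space(60, seed=0)


@pytest.fixture(scope="session")
def montage():
    return hm.standard_montage_1010()


@pytest.fixture(scope="session")
def small_leadfield(small_space, montage):
    return hm.analytic_three_shell_leadfield(small_space, montage)


@pytest.fixture(scope="session")
def tiny_bank():
    """Small balanced bank from a heavily thinned grid (fast)."""
    grid = nmm.GridSpec().thin(6)
    bank = nmm.explore_parameter_grid(grid, seed=0)
    return nmm.balance_parameter_sets(
        bank, per_type=4, train_count=16, test_count=4, seed=0
    )


@pytest.fixture(scope="session")
def reduced_bank():
    """Unbalanced bank from the reduced grid (every 4th value per axis)."""
    return nmm.explore_parameter_grid(nmm.GridSpec().thin(4), seed=0)


@pytest.fixture(scope="session")
def tiny_dataset(small_space, small_leadfield, tiny_bank):
    cfg = simulate.DatasetConfig(
        n_centers=6, variants_per_center=2, snr_levels=(5.0, 15.0),
        time_points=50, sample_rate=100.0, patch_size_range=(2, 5),
    )
    return simulate.generate_dataset(
        small_space, small_leadfield, tiny_bank, cfg, seed=0
    )


def line_graph_space(n=10, spacing_mm=10.0):
    """Frozen toy fixture: n regions on a line, known centroid geometry."""
    centroids = np.zeros((n, 3))
    centroids[:, 0] = np.arange(n) * spacing_mm / 1000.0
    rows = list(range(n - 1)) + list(range(1, n))
    cols = list(range(1, n)) + list(range(n - 1))
    adj = sparse.csr_matrix(
        (np.ones(len(rows), dtype=bool), (rows, cols)), shape=(n, n)
    )
    orient = np.tile([0.0, 0.0, 1.0], (n, 1))
    return hm.SourceSpace(centroids, adj, np.ones(n), orient, radius=np.nan)


@pytest.fixture()
def toy_space():
    return line_graph_space()


def cycle_graph_space(n=6):
    """n regions on a cycle; used for exhaustive patch-growing oracles."""
    centroids = np.c_[
        np.cos(2 * np.pi * np.arange(n) / n),
        np.sin(2 * np.pi * np.arange(n) / n),
        np.zeros(n),
    ] * 0.05
    rows = [i for i in range(n)] + [(i + 1) % n for i in range(n)]
    cols = [(i + 1) % n for i in range(n)] + [i for i in range(n)]
    adj = sparse.csr_matrix(
        (np.ones(len(rows), dtype=bool), (rows, cols)), shape=(n, n)
    )
    orient = np.tile([0.0, 0.0, 1.0], (n, 1))
    return hm.SourceSpace(centroids, adj, np.ones(n), orient, radius=np.nan)
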