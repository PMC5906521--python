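"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from explantca import ModelParams, PriorSpec, build_pilot_library, default_shape, make_initial_mass


def dense_gdnf_solve(occupancy, dg):
    """Independent oracle: assemble the 5-point-stencil linear system for
    the quasi-steady GDNF equation and solve it with a dense direct solver.

    Interior unknowns only; the boundary ring contributes Dirichlet data
    g = 1 to the right-hand side.  Intentionally naive (O(n^6) memory in
    grid side length) — only for small grids.
    """
    occ = np.asarray(occupancy, dtype=bool)
    n = occ.shape[0]
    idx = -np.ones((n, n), dtype=int)
    interior = [(i, j) for i in range(1, n - 1) for j in range(1, n - 1)]
    for k, (i, j) in enumerate(interior):
        idx[i, j] = k
    m = len(interior)
    A = np.zeros((m, m))
    b = np.zeros(m)
    for k, (i, j) in enumerate(interior):
        A[k, k] = -4.0 * dg - (1.0 if occ[i, j] else 0.0)
        for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            kk = idx[i + di, j + dj]
            if kk >= 0:
                A[k, kk] += dg
            else:
                b[k] -= dg  # boundary neighbour fixed at g = 1
    u = np.linalg.solve(A, b)
    g = np.ones((n, n))
    for k, (i, j) in enumerate(interior):
        g[i, j] = u[k]
    return g


def flood_fill_components(mask):
    """Independent largest-component oracle: BFS flood fill, 8-connected."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    comps = []
    n, m = mask.shape
    for si in range(n):
        for sj in range(m):
            if mask[si, sj] and not seen[si, sj]:
                stack = [(si, sj)]
                seen[si, sj] = True
                comp = []
                while stack:
                    i, j = stack.pop()
                    comp.append((i, j))
                    for di in (-1, 0, 1):
                        for dj in (-1, 0, 1):
                            ii, jj = i + di, j + dj
                            if 0 <= ii < n and 0 <= jj < m and mask[ii, jj] and not seen[ii, jj]:
                                seen[ii, jj] = True
                                stack.append((ii, jj))
                comps.append(comp)
    return comps


def random_occupancy(rng, n, density=0.3, clear_ring=True):
    occ = rng.random((n, n)) < density
    if clear_ring:
        occ[0, :] = occ[-1, :] = occ[:, 0] = occ[:, -1] = False
    return occ


SMALL_GRID = 48


@pytest.fixture(scope="session")
def small_params():
    """Cheap simulation settings used by pipeline-level unit tests."""
    return ModelParams(grid_size=SMALL_GRID)


@pytest.fixture(scope="session")
def small_mask(small_params):
    return make_initial_mass(default_shape(small_params.grid_size), small_params.grid_size)


@pytest.fixture(scope="session")
def tiny_library(small_params, small_mask):
    """A small but real pilot library (true simulations at prior draws)."""
    return build_pilot_library(
        PriorSpec(), m=30, n_replicates=2, sim_config=small_params,
        initial_mask=small_mask, seed=42,
    )
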