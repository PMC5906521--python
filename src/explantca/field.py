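"""Quasi-steady growth-factor (GDNF) field over an occupancy raster.

The dimensionless concentration ``g`` solves the steady reaction--diffusion
problem

.. math::

    d_g \\nabla^2 g = g \\cdot [\\text{site occupied}],

with ``g = 1`` clamped on the outermost ring of grid points: the culture
medium at the domain edge acts as an infinite growth-factor reservoir, and
epithelial cells take the factor up at a rate linear in its local
concentration.  ECM (unoccupied) sites neither produce nor consume, so the
field is discretely harmonic there.

Uptake is linear, so the steady state is a sparse linear system on the
5-point stencil.  It is solved by successive over-relaxation (SOR) sweeps,
warm-started from the previous step's field during a simulation, which is
both fast and faithful to a finite-difference relaxation treatment.

Unit convention: :func:`solve_gdnf` takes the diffusion coefficient in
*lattice* units (grid spacing = 1).  The simulation layer stores the
grid-size-independent domain coefficient ``d_g = D_G / (K_G L^2)`` and
converts via ``d_g_lattice(d_g, n)`` = ``d_g * (n - 1)**2`` (the domain is
the unit square, so the spacing is 1/(n-1)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "FieldParams",
    "GdnfField",
    "FieldConvergenceError",
    "solve_gdnf",
    "d_g_lattice",
]


class FieldConvergenceError(RuntimeError):
    """Raised when the relaxation solve does not reach tolerance.

    Carries the final scaled residual in :attr:`residual`.
    """

    def __init__(self, residual: float, iterations: int):
        super().__init__(
            f"GDNF solve did not converge: residual {residual:.3e} "
            f"after {iterations} iterations"
        )
        self.residual = residual
        self.iterations = iterations


@dataclass(frozen=True)
class FieldParams:
    """Solver settings.

    d_g is the diffusion coefficient in lattice units (unit grid spacing);
    tolerance is on the diagonally scaled max-norm residual of the discrete
    equation.
    """

    d_g: float
    tolerance: float = 1e-6
    max_iterations: int = 200_000

    def __post_init__(self):
        if not self.d_g > 0:
            raise ValueError(f"d_g must be positive, got {self.d_g}")
        if not self.tolerance > 0:
            raise ValueError(f"tolerance must be positive, got {self.tolerance}")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class GdnfField:
    """Solved dimensionless GDNF concentration.

    values lies in [0, 1] everywhere, equals 1 on the boundary ring, and
    satisfies the discrete equation to within ``residual``.
    """

    values: np.ndarray
    residual: float
    iterations: int = 0


def d_g_lattice(d_g_domain: float, grid_size: int) -> float:
    """Convert the domain-level diffusion coefficient to lattice units."""
    return d_g_domain * (grid_size - 1) ** 2


@njit(cache=True)
def _scaled_residual(g, occ, dg):
    n = g.shape[0]
    res = 0.0
    for i in range(1, n - 1):
        for j in range(1, n - 1):
            diag = 4.0 * dg + (1.0 if occ[i, j] else 0.0)
            lap = g[i - 1, j] + g[i + 1, j] + g[i, j - 1] + g[i, j + 1] - 4.0 * g[i, j]
            r = dg * lap
            if occ[i, j]:
                r -= g[i, j]
            r = abs(r) / diag
            if r > res:
                res = r
    return res


@njit(cache=True)
def _sor_sweeps(g, occ, dg, omega, n_sweeps):
    n = g.shape[0]
    for _ in range(n_sweeps):
        for i in range(1, n - 1):
            for j in range(1, n - 1):
                diag = 4.0 * dg + (1.0 if occ[i, j] else 0.0)
                rhs = dg * (g[i - 1, j] + g[i + 1, j] + g[i, j - 1] + g[i, j + 1])
                g[i, j] += omega * (rhs / diag - g[i, j])


# --- geometric multigrid acceleration -------------------------------------
# The discrete operator is A u = dg * lap(u) - c * u with c = [occupied];
# relaxation alone needs O(N) sweeps per digit on the harmonic (ECM)
# region, so large grids use a V-cycle: damped Gauss-Seidel smoothing,
# full-weighting restriction of the residual, bilinear prolongation of the
# coarse correction (zero Dirichlet), with the lattice coefficient scaled
# by 1/4 per coarsening (spacing doubles).  Convergence is still judged
# on the fine grid by the same scaled residual, so the accuracy contract
# is identical to plain SOR.


@njit(cache=True)
def _mg_smooth(u, c, dg, f, n_sweeps, omega):
    n = u.shape[0]
    for _ in range(n_sweeps):
        for i in range(1, n - 1):
            for j in range(1, n - 1):
                diag = 4.0 * dg + c[i, j]
                rhs = dg * (u[i - 1, j] + u[i + 1, j] + u[i, j - 1] + u[i, j + 1]) - f[i, j]
                u[i, j] += omega * (rhs / diag - u[i, j])


@njit(cache=True)
def _mg_residual(u, c, dg, f, out):
    n = u.shape[0]
    for i in range(1, n - 1):
        for j in range(1, n - 1):
            lap = u[i - 1, j] + u[i + 1, j] + u[i, j - 1] + u[i, j + 1] - 4.0 * u[i, j]
            out[i, j] = f[i, j] - (dg * lap - c[i, j] * u[i, j])


@njit(cache=True)
def _mg_restrict(fine, coarse):
    """Full-weighting restriction at coarse points (2i, 2j)."""
    nc = coarse.shape[0]
    nf = fine.shape[0]
    for i in range(1, nc - 1):
        for j in range(1, nc - 1):
            fi = 2 * i
            fj = 2 * j
            if fi >= nf - 1 or fj >= nf - 1:
                coarse[i, j] = 0.0
                continue
            s = 4.0 * fine[fi, fj]
            s += 2.0 * (fine[fi - 1, fj] + fine[fi + 1, fj] + fine[fi, fj - 1] + fine[fi, fj + 1])
            s += fine[fi - 1, fj - 1] + fine[fi - 1, fj + 1] + fine[fi + 1, fj - 1] + fine[fi + 1, fj + 1]
            coarse[i, j] = s / 16.0


@njit(cache=True)
def _mg_prolong_add(fine, coarse):
    """Bilinear interpolation of the coarse correction added into fine."""
    nc = coarse.shape[0]
    nf = fine.shape[0]
    for i in range(1, nf - 1):
        ci = i // 2
        ri = i - 2 * ci  # 0 at coarse points, 1 between
        for j in range(1, nf - 1):
            cj = j // 2
            rj = j - 2 * cj
            ci1 = min(ci + ri, nc - 1)
            cj1 = min(cj + rj, nc - 1)
            ci0 = min(ci, nc - 1)
            cj0 = min(cj, nc - 1)
            fine[i, j] += 0.25 * (
                coarse[ci0, cj0] + coarse[ci1, cj0] + coarse[ci0, cj1] + coarse[ci1, cj1]
            )


class _MgHierarchy:
    """Per-grid-size scratch arrays for the V-cycle."""

    def __init__(self, n: int, occ: np.ndarray):
        self.sizes = []
        self.c = []
        m = n
        c_fine = occ.astype(np.float64)
        while m >= 9:
            self.sizes.append(m)
            self.c.append(c_fine)
            mc = (m + 1) // 2
            c_coarse = np.zeros((mc, mc))
            _mg_restrict(c_fine, c_coarse)
            np.clip(c_coarse, 0.0, 1.0, out=c_coarse)
            c_fine = c_coarse
            m = mc
        self.sizes.append(m)
        self.c.append(c_fine)
        self.f = [np.zeros((m, m)) for m in self.sizes]
        self.r = [np.zeros((m, m)) for m in self.sizes]
        self.e = [np.zeros((m, m)) for m in self.sizes]


def _vcycle(h: _MgHierarchy, g: np.ndarray, dg: float, omega: float = 1.25):
    levels = len(h.sizes)
    us = [g] + h.e[1:]
    for lev in range(levels - 1):
        dgl = dg / 4.0**lev
        if lev > 0:
            us[lev][:] = 0.0
        _mg_smooth(us[lev], h.c[lev], dgl, h.f[lev], 2, omega)
        _mg_residual(us[lev], h.c[lev], dgl, h.f[lev], h.r[lev])
        _mg_restrict(h.r[lev], h.f[lev + 1])
    # coarsest: relax hard (grid is tiny)
    us[-1][:] = 0.0
    _mg_smooth(us[-1], h.c[-1], dg / 4.0 ** (levels - 1), h.f[-1], 60, 1.0)
    for lev in range(levels - 2, -1, -1):
        _mg_prolong_add(us[lev], us[lev + 1])
        _mg_smooth(us[lev], h.c[lev], dg / 4.0**lev, h.f[lev], 2, omega)


def solve_gdnf(occupancy, params: FieldParams, warm_start: GdnfField | None = None) -> GdnfField:
    """Solve the quasi-steady GDNF equation over ``occupancy``.

    Parameters
    ----------
    occupancy
        N x N boolean raster, True where an epithelial cell sits. N >= 3.
    params
        Solver settings (lattice-unit ``d_g``, tolerance, iteration cap).
    warm_start
        Optional previously solved field of matching shape used as the
        initial iterate; inside a simulation the occupancy changes little
        per step, so this typically cuts the solve cost by an order of
        magnitude.

    Returns
    -------
    GdnfField
        Field with values in [0, 1], boundary ring exactly 1, and scaled
        max-norm residual <= ``params.tolerance``.

    Raises
    ------
    ValueError
        Non-square or smaller-than-3x3 raster, or warm-start shape mismatch.
    FieldConvergenceError
        Tolerance not reached within ``params.max_iterations`` sweeps.

    Notes
    -----
    An occupied site on the clamped boundary ring keeps g = 1 there: the
    Dirichlet condition wins over uptake.  The returned values are clipped
    to [0, 1]; any excursion outside the physical range is an iteration
    artefact bounded by the residual tolerance.
    """
    occ = np.asarray(occupancy)
    if occ.ndim != 2 or occ.shape[0] != occ.shape[1]:
        raise ValueError(f"occupancy must be a square 2-D raster, got shape {occ.shape}")
    n = occ.shape[0]
    if n < 3:
        raise ValueError(f"grid must be at least 3x3, got {n}x{n}")
    occ = occ.astype(bool)

    if warm_start is not None:
        if warm_start.values.shape != occ.shape:
            raise ValueError(
                f"warm_start shape {warm_start.values.shape} does not match occupancy {occ.shape}"
            )
        g = warm_start.values.astype(np.float64, copy=True)
    else:
        g = np.ones((n, n), dtype=np.float64)
    # Dirichlet ring
    g[0, :] = 1.0
    g[-1, :] = 1.0
    g[:, 0] = 1.0
    g[:, -1] = 1.0

    dg = float(params.d_g)
    done = 0
    res = _scaled_residual(g, occ, dg)
    if n >= 33:
        # multigrid path: one V-cycle counts as its fine-level smoothing work
        h = _MgHierarchy(n, occ)
        while res > params.tolerance:
            if done >= params.max_iterations:
                raise FieldConvergenceError(res, done)
            _vcycle(h, g, dg)
            done += 4
            res = _scaled_residual(g, occ, dg)
    else:
        omega = 2.0 / (1.0 + math.sin(math.pi / (n - 1)))
        stride = 16
        while res > params.tolerance:
            if done >= params.max_iterations:
                raise FieldConvergenceError(res, done)
            todo = min(stride, params.max_iterations - done)
            _sor_sweeps(g, occ, dg, omega, todo)
            done += todo
            res = _scaled_residual(g, occ, dg)

    np.clip(g, 0.0, 1.0, out=g)
    return GdnfField(values=g, residual=res, iterations=done)
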