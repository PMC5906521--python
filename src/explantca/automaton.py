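"""Lattice cellular automaton of the branching epithelium.

Each site of an N x N grid holds either an epithelial cell or ECM.  Once
per step, every cell present at the start of the step is visited in a
fresh uniformly random order.  A cell with at least one empty von Neumann
neighbour proposes a move (probability ``p_move``) or a division
(probability ``1 - p_move``):

* moves are always executed; the destination among the empty neighbours is
  drawn from a softmax over their GDNF levels with sensitivity
  ``beta_move`` (chemotaxis; uniform when the mechanism is off),
* a division fires with probability ``Phi(c1 + c2 * g)`` where ``g`` is
  the GDNF level at the mother's own site and ``Phi`` the standard normal
  CDF — a probit switch whose midpoint sits at ``g = -c1/c2``; the
  daughter's site is drawn from the same softmax with ``beta_div``
  (anisotropic cell division).

Cell death is neglected, so the cell count never decreases.  The clamped
boundary ring of the GDNF solve is treated like off-grid space: cells
never move or divide onto it.

The per-step field/automaton coupling lives in :func:`simulate`: the
quasi-steady GDNF field is re-solved once per step for the current
occupancy, then all cells are updated against that frozen field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field, replace

import numpy as np
from numba import njit
from scipy.special import ndtr

from .field import FieldParams, GdnfField, d_g_lattice, solve_gdnf

__all__ = [
    "ModelParams",
    "LatticeState",
    "Trajectory",
    "division_probability",
    "site_selection_probs",
    "step",
    "simulate",
]


@dataclass(frozen=True)
class ModelParams:
    """All CA/field constants and mechanism toggles.

    ``d_g`` is the domain-level nondimensional diffusion coefficient
    (converted internally to lattice units, so the GDNF penetration
    depth scales with the grid and the default dynamical regime is
    grid-size invariant).  ``c1``/``c2`` set the
    location and steepness of the probit division switch;
    ``p_move`` is the probability that a proposed action is a move;
    ``beta_move``/``beta_div`` the softmax sensitivities of chemotaxis
    and anisotropic daughter placement.  The three toggles correspond to
    the mechanism-ablation rows: GDNF-stimulated division, chemotaxis,
    and anisotropic cell division (ACD).  When ``gdnf_division`` is off
    divisions fire with the flat probability ``p_const``; when a softmax
    toggle is off the corresponding beta is treated as 0 (uniform
    neighbour choice).  ``steps_per_hour`` maps CA sweeps to simulated
    hours.
    """

    grid_size: int = 120
    d_g: float = 0.00075
    c1: float = -25.0
    c2: float = 120.0
    p_move: float = 0.2
    beta_move: float = 20.0
    beta_div: float = 50.0
    gdnf_division: bool = True
    chemotaxis: bool = True
    acd: bool = True
    p_const: float = 0.1
    attachment_rule: bool = False
    steps_per_hour: float = 1.5
    field_tolerance: float = 1e-6
    field_max_iterations: int = 200_000

    def __post_init__(self):
        if self.grid_size < 3:
            raise ValueError("grid_size must be >= 3")
        if not self.d_g > 0:
            raise ValueError("d_g must be positive")
        for name in ("p_move", "p_const"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("beta_move", "beta_div"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not self.steps_per_hour > 0:
            raise ValueError("steps_per_hour must be positive")

    def field_params(self) -> FieldParams:
        """Solver settings with ``d_g`` converted to lattice units."""
        return FieldParams(
            d_g=d_g_lattice(self.d_g, self.grid_size),
            tolerance=self.field_tolerance,
            max_iterations=self.field_max_iterations,
        )


@dataclass
class LatticeState:
    """Occupancy raster plus the step counter and the simulation RNG."""

    occupancy: np.ndarray
    step_index: int = 0
    rng: np.random.Generator = dc_field(default_factory=np.random.default_rng)


@dataclass
class Trajectory:
    """Recorded occupancy snapshots of one simulation.

    ``times_h`` are strictly increasing recorded times (the first is the
    initial mass at t = 0 when requested); ``snapshots`` are boolean
    occupancy rasters; ``fields`` optionally carries the matching GDNF
    fields.
    """

    times_h: np.ndarray
    snapshots: list
    fields: list | None = None

    def __len__(self):
        return len(self.snapshots)


def division_probability(g_local, c1, c2):
    """Probit division switch: Phi(c1 + c2 * g_local).

    The standard normal CDF of the affinely transformed local GDNF level.
    With c1 < 0 < c2 this is a sigmoidal switch with midpoint at
    g = -c1/c2 and steepness set by c2; at g = 0 division is effectively
    shut off for the default parameters.
    """
    return ndtr(c1 + c2 * np.asarray(g_local, dtype=float))[()]


def site_selection_probs(g_neighbours, beta):
    """Softmax site-selection probabilities over empty neighbour sites.

    p_i = exp(beta * g_i) / sum_j exp(beta * g_j), ordered as the input.
    beta = 0 gives the uniform vector; large beta concentrates on the
    highest-GDNF site.
    """
    g = np.asarray(g_neighbours, dtype=float)
    if g.ndim != 1 or g.size == 0:
        raise ValueError("g_neighbours must be a non-empty 1-D sequence")
    if beta < 0:
        raise ValueError("beta must be non-negative")
    z = beta * g
    z -= z.max()
    w = np.exp(z)
    return w / w.sum()


@njit(cache=True)
def _phi(x):
    return 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))


@njit(cache=True)
def _pick_site(g, nbr_r, nbr_c, k, beta, u):
    """Inverse-CDF draw from the softmax over the first k candidate sites."""
    zmax = -1.0e300
    for i in range(k):
        z = beta * g[nbr_r[i], nbr_c[i]]
        if z > zmax:
            zmax = z
    total = 0.0
    w = np.empty(k, np.float64)
    for i in range(k):
        w[i] = math.exp(beta * g[nbr_r[i], nbr_c[i]] - zmax)
        total += w[i]
    acc = 0.0
    for i in range(k):
        acc += w[i] / total
        if u < acc:
            return i
    return k - 1


@njit(cache=True)
def _sweep(occ, g, rows, cols, perm, u_action, u_gate, u_site,
           p_move, c1, c2, use_gdnf_division, p_const,
           beta_move, beta_div, attachment):
    """One CA step over a frozen permutation of the cells present at entry.

    Mutates ``occ`` and the (rows, cols) cell coordinates in place;
    daughters are appended to the occupancy only (they are not revisited
    within this sweep).  Returns the number of successful divisions.
    """
    n = occ.shape[0]
    ncells = rows.shape[0]
    nbr_r = np.empty(4, np.int64)
    nbr_c = np.empty(4, np.int64)
    dr = (-1, 1, 0, 0)
    dc = (0, 0, -1, 1)
    ndiv = 0
    for t in range(ncells):
        j = perm[t]
        r = rows[j]
        c = cols[j]
        k = 0
        for q in range(4):
            rr = r + dr[q]
            cc = c + dc[q]
            # the clamped boundary ring is unavailable, like off-grid space
            if 1 <= rr <= n - 2 and 1 <= cc <= n - 2 and not occ[rr, cc]:
                nbr_r[k] = rr
                nbr_c[k] = cc
                k += 1
        if k == 0:
            continue
        if u_action[t] < p_move:
            i = _pick_site(g, nbr_r, nbr_c, k, beta_move, u_site[t])
            rr = nbr_r[i]
            cc = nbr_c[i]
            if attachment:
                ok = False
                for q in range(4):
                    ar = rr + dr[q]
                    ac = cc + dc[q]
                    if 0 <= ar < n and 0 <= ac < n and occ[ar, ac]:
                        if not (ar == r and ac == c):
                            ok = True
                            break
                if not ok:
                    continue
            occ[r, c] = False
            occ[rr, cc] = True
            rows[j] = rr
            cols[j] = cc
        else:
            if use_gdnf_division:
                p = _phi(c1 + c2 * g[r, c])
            else:
                p = p_const
            if u_gate[t] < p:
                i = _pick_site(g, nbr_r, nbr_c, k, beta_div, u_site[t])
                occ[nbr_r[i], nbr_c[i]] = True
                ndiv += 1
    return ndiv


def step(state: LatticeState, gdnf: GdnfField, params: ModelParams) -> LatticeState:
    """Advance the automaton by one sweep against a solved GDNF field.

    Every cell present at entry is visited exactly once, in a fresh
    uniformly random permutation drawn from the state's RNG.  The RNG is
    consumed in a fixed order (permutation, action uniforms, gate
    uniforms, site uniforms) so that runs are bit-reproducible.

    Returns a new :class:`LatticeState`; the input occupancy is left
    untouched.  Raises ``ValueError`` on a field/occupancy shape mismatch.
    """
    occ = state.occupancy
    if gdnf.values.shape != occ.shape:
        raise ValueError(
            f"field shape {gdnf.values.shape} does not match occupancy {occ.shape}"
        )
    rows, cols = np.nonzero(occ)
    rows = rows.astype(np.int64)
    cols = cols.astype(np.int64)
    n_cells = rows.size
    new_occ = occ.copy()
    if n_cells:
        rng = state.rng
        perm = rng.permutation(n_cells)
        u_action = rng.random(n_cells)
        u_gate = rng.random(n_cells)
        u_site = rng.random(n_cells)
        beta_move = params.beta_move if params.chemotaxis else 0.0
        beta_div = params.beta_div if params.acd else 0.0
        _sweep(
            new_occ, gdnf.values, rows, cols, perm, u_action, u_gate, u_site,
            params.p_move, params.c1, params.c2, params.gdnf_division,
            params.p_const, beta_move, beta_div, params.attachment_rule,
        )
    return LatticeState(occupancy=new_occ, step_index=state.step_index + 1, rng=state.rng)


def simulate(initial_mask, params: ModelParams, record_times_h, seed,
             record_fields: bool = False) -> Trajectory:
    """Run the coupled field/automaton model and record snapshots.

    Parameters
    ----------
    initial_mask
        Boolean N x N raster of the starting epithelial mass; must match
        ``params.grid_size`` and keep clear of the clamped boundary ring.
    params
        Model constants and mechanism toggles.
    record_times_h
        Times (hours) at which to record occupancy; each is mapped to the
        nearest CA step via ``params.steps_per_hour``.
    seed
        Seed of the single RNG stream driving all stochastic choices.
    record_fields
        If True, also record the solved GDNF field at each recorded time.

    Returns
    -------
    Trajectory
        Snapshots in increasing time order.  Identical
        (mask, params, seed) give bit-identical trajectories.
    """
    occ0 = np.asarray(initial_mask).astype(bool)
    n = params.grid_size
    if occ0.shape != (n, n):
        raise ValueError(f"initial_mask shape {occ0.shape} does not match grid {n}x{n}")
    if not occ0.any():
        raise ValueError("initial_mask has no cells")
    border = occ0[0, :].any() or occ0[-1, :].any() or occ0[:, 0].any() or occ0[:, -1].any()
    if border:
        raise ValueError("initial_mask touches the clamped boundary ring")

    times = np.asarray(list(record_times_h), dtype=float)
    if times.size == 0:
        raise ValueError("record_times_h must be non-empty")
    if np.any(times < 0):
        raise ValueError("record times must be non-negative")
    order = np.argsort(times, kind="stable")
    times = times[order]
    record_steps = np.rint(times * params.steps_per_hour).astype(int)

    fp = params.field_params()
    state = LatticeState(occupancy=occ0.copy(), rng=np.random.default_rng(seed))
    gdnf: GdnfField | None = None

    snapshots: list[np.ndarray] = []
    fields: list[GdnfField] = []
    rec = {}
    for s, t in zip(record_steps, times):
        rec.setdefault(int(s), []).append(t)

    def _record(step_idx):
        for _t in rec.get(step_idx, []):
            snapshots.append(state.occupancy.copy())
            if record_fields:
                # re-solve so the stored field matches the stored occupancy
                fields.append(solve_gdnf(state.occupancy, fp, warm_start=gdnf))

    _record(0)
    for s in range(1, int(record_steps.max()) + 1):
        gdnf = solve_gdnf(state.occupancy, fp, warm_start=gdnf)
        state = step(state, gdnf, params)
        _record(s)

    return Trajectory(
        times_h=times,
        snapshots=snapshots,
        fields=fields if record_fields else None,
    )
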