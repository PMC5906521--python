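"""Synthetic stand-ins for the undeposited explant imaging data.

The original ex vivo movies (GFP-labelled ureteric bud explants imaged
over tens of hours) are not publicly deposited, so every test input is
generated here: deterministic initial-mass rasters shaped like an early
explant (a blob with incipient buds), simple geometric shapes with known
skeleton topology, and self-consistent "observed" summary trajectories
produced by running the real simulator at a known parameter triple.

Everything is reproducible from (spec, seed) alone.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .automaton import ModelParams, simulate
from .morphometrics import SummaryDataset, summarise_trajectory

__all__ = [
    "ShapeSpec",
    "make_initial_mass",
    "default_shape",
    "make_reference_observed",
    "DEFAULT_OBSERVED_TIMES_H",
]

DEFAULT_OBSERVED_TIMES_H = (10.0, 20.0, 30.0)

# shapes must keep this margin to the clamped boundary ring
_MARGIN = 10


@dataclass(frozen=True)
class ShapeSpec:
    """Parameterised initial-mass shape.

    kind is one of {"ellipse", "t_bud", "cross", "from_file"}; ``a`` and
    ``b`` are semi-axes (ellipse, t_bud body) or arm half-length / arm
    half-width (cross) in pixels; ``offset`` shifts the centre by
    (rows, cols); ``path`` is used by "from_file" (a 0/255 PNG mask).
    """

    kind: str = "t_bud"
    a: float = 12.0
    b: float = 6.0
    offset: tuple = (0, 0)
    path: str | None = None

    def __post_init__(self):
        if self.kind not in {"ellipse", "t_bud", "cross", "from_file"}:
            raise ValueError(f"unknown shape kind {self.kind!r}")
        if self.kind != "from_file" and (self.a <= 0 or self.b <= 0):
            raise ValueError("shape size parameters must be positive")


def _ellipse(n, cy, cx, a, b):
    yy, xx = np.mgrid[0:n, 0:n]
    return ((yy - cy) / b) ** 2 + ((xx - cx) / a) ** 2 <= 1.0


def _disk(n, cy, cx, r):
    yy, xx = np.mgrid[0:n, 0:n]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


def make_initial_mass(spec: ShapeSpec, grid_size: int) -> np.ndarray:
    """Rasterise the requested shape onto a grid, centred plus offset.

    Deterministic; raises ``ValueError`` if the shape comes within 10
    pixels of the clamped boundary ring.
    """
    n = int(grid_size)
    if n < 2 * _MARGIN + 3:
        raise ValueError(f"grid_size {n} too small for any admissible shape")
    cy = n / 2 + spec.offset[0]
    cx = n / 2 + spec.offset[1]

    if spec.kind == "ellipse":
        mask = _ellipse(n, cy, cx, spec.a, spec.b)
    elif spec.kind == "t_bud":
        # horizontal elliptical bud body with two incipient lobes on top,
        # echoing an early explant: a bulk mass already showing buds
        body = _ellipse(n, cy, cx, spec.a, spec.b)
        r = 0.8 * spec.b
        lobes = _disk(n, cy - 0.9 * spec.b, cx - 0.55 * spec.a, r) | _disk(
            n, cy - 0.9 * spec.b, cx + 0.55 * spec.a, r
        )
        mask = body | lobes
    elif spec.kind == "cross":
        # two perpendicular bars: arm half-length a, half-width b
        yy, xx = np.mgrid[0:n, 0:n]
        horiz = (np.abs(yy - cy) <= spec.b) & (np.abs(xx - cx) <= spec.a)
        vert = (np.abs(xx - cx) <= spec.b) & (np.abs(yy - cy) <= spec.a)
        mask = horiz | vert
    elif spec.kind == "from_file":
        if spec.path is None:
            raise ValueError("from_file shape needs a path")
        import imageio.v3 as iio

        img = np.asarray(iio.imread(spec.path))
        if img.ndim == 3:
            img = img[..., 0]
        mask = img > 0
        if mask.shape != (n, n):
            raise ValueError(
                f"mask file shape {mask.shape} does not match grid {n}x{n}"
            )
    else:  # pragma: no cover - guarded in ShapeSpec
        raise ValueError(spec.kind)

    if not mask.any():
        raise ValueError("rasterised shape is empty")
    rows, cols = np.nonzero(mask)
    if (rows.min() < _MARGIN or cols.min() < _MARGIN
            or rows.max() >= n - _MARGIN or cols.max() >= n - _MARGIN):
        raise ValueError(
            f"shape must keep a {_MARGIN}-pixel margin to the boundary ring"
        )
    return mask


def default_shape(grid_size: int) -> ShapeSpec:
    """Explant-like starting mass scaled to the grid (body ~1/5 of it)."""
    return ShapeSpec(kind="t_bud", a=0.10 * grid_size, b=0.05 * grid_size)


def make_reference_observed(theta_true, sim_config: ModelParams, n_replicates: int,
                            seed: int, times_h=DEFAULT_OBSERVED_TIMES_H,
                            shape: ShapeSpec | None = None):
    """Synthetic "observed" dataset from the real simulator at a known truth.

    Runs ``n_replicates`` simulations at ``theta_true = (c1, c2, p_move)``
    (all other constants from ``sim_config``), summarises them at
    ``times_h``, and returns ``(datasets, truth)`` where ``truth`` records
    the generating parameters for recovery tests.
    """
    c1, c2, p_move = (float(v) for v in theta_true)
    params = replace(sim_config, c1=c1, c2=c2, p_move=p_move)
    if shape is None:
        shape = default_shape(params.grid_size)
    mask = make_initial_mass(shape, params.grid_size)
    rng = np.random.default_rng(seed)
    sim_seeds = rng.integers(0, 2**31 - 1, size=n_replicates)
    record = [0.0] + [t for t in times_h if t > 0]
    datasets: list[SummaryDataset] = []
    for i, s in enumerate(sim_seeds):
        traj = simulate(mask, params, record, seed=int(s))
        datasets.append(summarise_trajectory(traj, times_h, replicate_id=i))
    truth = {"c1": c1, "c2": c2, "p_move": p_move, "seed": int(seed)}
    return datasets, truth
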