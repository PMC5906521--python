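"""Approximate Approximate Bayesian Computation (AABC).

Likelihood-free inference of the automaton parameters
``theta = (c1, c2, p_move)`` from observed summary statistics
(normalised area and branch count at a few time points), where each true
simulation is expensive.  A *pilot library* of m true simulations at
prior draws is built once; thereafter each proposal theta* is evaluated
without simulating: the k pilot particles nearest to theta* (Euclidean
distance after rescaling each parameter to unit prior range) receive
Epanechnikov kernel weights, a Dirichlet draw over those weights sets
resampling probabilities, and a pseudo-dataset is assembled by resampling
whole replicate summary vectors from the selected particles.  Proposals
whose pseudo-data lie within the acceptance-quantile distance of the
observed data form the posterior sample.

Summary-space distances are taken between replicate means, with each
dimension standardised by the pilot-library standard deviation (raw
distances otherwise being dominated by branch counts); raw mode is
available via ``standardise=False``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .automaton import ModelParams, simulate
from .morphometrics import SummaryDataset, summarise_trajectory

__all__ = [
    "PriorSpec",
    "PilotLibrary",
    "PosteriorSample",
    "DegenerateKernelError",
    "build_pilot_library",
    "epanechnikov_weights",
    "pseudo_dataset",
    "aabc_infer",
    "summaries_to_array",
]

PARAM_NAMES = ("c1", "c2", "p_move")


class DegenerateKernelError(ValueError):
    """theta* duplicated by >= k+1 pilot particles: kernel bandwidth is 0."""


@dataclass(frozen=True)
class PriorSpec:
    """Independent uniform priors over (c1, c2, p_move)."""

    c1: tuple = (-40.0, -20.0)
    c2: tuple = (40.0, 280.0)
    p_move: tuple = (0.0, 1.0)

    def __post_init__(self):
        for name in PARAM_NAMES:
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"prior for {name} needs low < high, got ({lo}, {hi})")

    @property
    def bounds(self) -> np.ndarray:
        return np.array([self.c1, self.c2, self.p_move], dtype=float)

    @property
    def ranges(self) -> np.ndarray:
        b = self.bounds
        return b[:, 1] - b[:, 0]

    @property
    def mean(self) -> np.ndarray:
        return self.bounds.mean(axis=1)

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        b = self.bounds
        return rng.uniform(b[:, 0], b[:, 1], size=(size, 3))

    def contains(self, theta) -> bool:
        t = np.asarray(theta, dtype=float)
        b = self.bounds
        return bool(np.all(t >= b[:, 0]) and np.all(t <= b[:, 1]))


@dataclass
class PilotLibrary:
    """(theta_i, x_i) pairs from true simulations at prior draws.

    ``thetas`` is (m, 3); ``summaries`` is (m, N, D) with N replicates of
    D-dimensional summary vectors per particle, all at ``times_h``.
    """

    thetas: np.ndarray
    summaries: np.ndarray
    times_h: np.ndarray
    prior: PriorSpec

    def __post_init__(self):
        self.thetas = np.asarray(self.thetas, dtype=float)
        self.summaries = np.asarray(self.summaries, dtype=float)
        if self.thetas.ndim != 2 or self.thetas.shape[1] != 3:
            raise ValueError("thetas must be (m, 3)")
        if self.summaries.ndim != 3 or self.summaries.shape[0] != self.thetas.shape[0]:
            raise ValueError("summaries must be (m, N, D) matching thetas")

    @property
    def m(self) -> int:
        return self.thetas.shape[0]

    @property
    def n_replicates(self) -> int:
        return self.summaries.shape[1]

    def summary_scale(self) -> np.ndarray:
        """Per-dimension std of pilot replicate means (zeros mapped to 1)."""
        scale = self.summaries.mean(axis=1).std(axis=0)
        return np.where(scale > 0, scale, 1.0)


@dataclass
class PosteriorSample:
    """Accepted theta* draws with their distances and the threshold used."""

    thetas: np.ndarray
    distances: np.ndarray
    epsilon: float
    acceptance_fraction: float
    all_distances: np.ndarray | None = None

    @property
    def n_accepted(self) -> int:
        return self.thetas.shape[0]

    def mean(self) -> np.ndarray:
        return self.thetas.mean(axis=0)


def summaries_to_array(datasets) -> np.ndarray:
    """Stack SummaryDataset replicates into an (N, D) array."""
    if isinstance(datasets, np.ndarray):
        return np.atleast_2d(np.asarray(datasets, dtype=float))
    if isinstance(datasets, SummaryDataset):
        datasets = [datasets]
    return np.stack([d.vector() for d in datasets])


def build_pilot_library(prior: PriorSpec, m: int, n_replicates: int,
                        sim_config: ModelParams, initial_mask, seed: int,
                        times_h=(10.0, 20.0, 30.0)) -> PilotLibrary:
    """Simulate the automaton at m prior draws to seed AABC.

    Each of the m parameter triples is drawn uniformly from the prior and
    simulated ``n_replicates`` times from ``initial_mask``; every particle
    is kept unless its simulation fails (then it is dropped with a
    warning).  Fixed ``seed`` gives an identical library on rerun.
    """
    if m < 2:
        raise ValueError("pilot library needs m >= 2")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    thetas = prior.sample(rng, m)
    sim_seeds = rng.integers(0, 2**31 - 1, size=(m, n_replicates))
    record = [0.0] + [t for t in times_h if t > 0]

    kept_thetas = []
    kept_summaries = []
    for i in range(m):
        params = replace(
            sim_config, c1=thetas[i, 0], c2=thetas[i, 1], p_move=thetas[i, 2]
        )
        try:
            reps = []
            for j in range(n_replicates):
                traj = simulate(initial_mask, params, record, seed=int(sim_seeds[i, j]))
                reps.append(summarise_trajectory(traj, times_h, replicate_id=j).vector())
        except Exception as exc:  # noqa: BLE001 - any sim failure drops the particle
            warnings.warn(
                f"pilot particle {i} (theta={thetas[i]}) dropped: {exc}",
                stacklevel=2,
            )
            continue
        kept_thetas.append(thetas[i])
        kept_summaries.append(np.stack(reps))
    if len(kept_thetas) < 2:
        raise RuntimeError("too few pilot particles survived simulation")
    return PilotLibrary(
        thetas=np.stack(kept_thetas),
        summaries=np.stack(kept_summaries),
        times_h=np.asarray(times_h, dtype=float),
        prior=prior,
    )


def epanechnikov_weights(theta_star, library: PilotLibrary, k: int) -> np.ndarray:
    """Epanechnikov kernel weights of the k pilot particles nearest theta*.

    Distances are Euclidean after rescaling each parameter to unit prior
    range.  With d_(k+1) the (k+1)-th smallest distance (ties resolved by
    index), the i-th weight is

        w_i = (3/4) (1/d_(k+1)) (1 - (d_i / d_(k+1))**2)

    for the k nearest particles and exactly 0 from the (k+1)-th onwards.
    A selected particle lying exactly at the bandwidth (a tie across the
    cutoff) gets the smallest positive weight representable by the kernel
    rather than 0, honouring the index tie-break.

    Raises :class:`DegenerateKernelError` when d_(k+1) = 0.
    """
    if not 1 <= k < library.m:
        raise ValueError(f"k must satisfy 1 <= k < m, got k={k}, m={library.m}")
    theta = np.asarray(theta_star, dtype=float).reshape(3)
    scale = library.prior.ranges
    d = np.linalg.norm((library.thetas - theta) / scale, axis=1)
    order = np.argsort(d, kind="stable")
    bandwidth = d[order[k]]
    if bandwidth == 0.0:
        raise DegenerateKernelError(
            "theta* coincides with >= k+1 pilot particles; kernel bandwidth is 0"
        )
    w = np.zeros(library.m)
    sel = order[:k]
    d_sel = np.minimum(d[sel], np.nextafter(bandwidth, 0.0))
    w[sel] = 0.75 / bandwidth * (1.0 - (d_sel / bandwidth) ** 2)
    return w


def pseudo_dataset(library: PilotLibrary, weights, n_replicates: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Resample a pseudo-dataset x* of replicate summary vectors.

    A Dirichlet draw parameterised by the positive weights sets the
    particle resampling probabilities phi; each output replicate picks a
    particle from phi and then one of its stored replicates uniformly.
    Output rows are members of the pilot datasets (no interpolation).
    """
    w = np.asarray(weights, dtype=float)
    if w.shape != (library.m,):
        raise ValueError("weights length must equal library size")
    pos = np.flatnonzero(w > 0)
    if pos.size == 0:
        raise ValueError("need at least one positive weight")
    phi = rng.dirichlet(w[pos])
    particles = pos[rng.choice(pos.size, size=n_replicates, p=phi)]
    reps = rng.integers(0, library.n_replicates, size=n_replicates)
    return library.summaries[particles, reps]


def aabc_infer(observed, prior: PriorSpec, library: PilotLibrary,
               n_proposals: int, k: int = 50, accept_quantile: float = 0.05,
               seed: int = 0, standardise: bool = True) -> PosteriorSample:
    """Run the AABC rejection loop and return the posterior sample.

    Parameters
    ----------
    observed
        SummaryDataset(s) or an (N, D) array at the library's time
        points; replicates are averaged before distance computation.
    prior, library
        The prior the proposals are drawn from and the pilot library the
        pseudo-data are resampled from (they must share time points).
    n_proposals
        Number of theta* proposals.
    k
        Number of nearest pilot particles kernel-weighted per proposal.
    accept_quantile
        epsilon is set to this quantile of the proposal distances, so
        this fraction of proposals is accepted (up to integer rounding).
    seed
        Seed for the proposal/resampling RNG.
    standardise
        Standardise summary dimensions by pilot-library standard
        deviations before the Euclidean distance (recommended).
    """
    if not 0.0 < accept_quantile <= 1.0:
        raise ValueError("accept_quantile must lie in (0, 1]")
    if n_proposals < 1:
        raise ValueError("n_proposals must be >= 1")
    obs = summaries_to_array(observed)
    d_dim = library.summaries.shape[2]
    if obs.shape[1] != d_dim:
        raise ValueError(
            f"observed dimension {obs.shape[1]} does not match library {d_dim} "
            "(check the summary time points)"
        )
    obs_mean = obs.mean(axis=0)
    scale = library.summary_scale() if standardise else np.ones(d_dim)

    rng = np.random.default_rng(seed)
    thetas = prior.sample(rng, n_proposals)
    dists = np.empty(n_proposals)
    n_rep = library.n_replicates
    for i in range(n_proposals):
        w = epanechnikov_weights(thetas[i], library, k)
        x_star = pseudo_dataset(library, w, n_rep, rng)
        dists[i] = np.linalg.norm((obs_mean - x_star.mean(axis=0)) / scale)

    n_accept = int(round(accept_quantile * n_proposals))
    n_accept = max(1, min(n_accept, n_proposals))
    order = np.argsort(dists, kind="stable")
    accepted = order[:n_accept]
    # epsilon is the smallest distance strictly above the accepted set, so
    # every accepted distance < epsilon even when pseudo-data ties produce
    # repeated distances (rank ties are broken by proposal index)
    if n_accept < n_proposals:
        above = dists[order[n_accept:]]
        above = above[above > dists[order[n_accept - 1]]]
        epsilon = float(above.min()) if above.size else np.inf
    else:
        epsilon = np.inf
    return PosteriorSample(
        thetas=thetas[accepted],
        distances=dists[accepted],
        epsilon=epsilon,
        acceptance_fraction=n_accept / n_proposals,
        all_distances=dists,
    )
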