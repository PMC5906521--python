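# Methods

## Model

The simulator couples a lattice cellular automaton of epithelial cells
to a quasi-steady diffusible growth-factor field on the same N×N grid.

**Field.** The dimensionless GDNF concentration g solves
`d_g ∇²g = g·[occupied]` with `g = 1` clamped on the outermost ring of
grid points (the culture medium as a far-field reservoir) and linear
uptake at cell-occupied sites.  The quasi-steady-state approximation
reflects the separation of time scales between morphogen diffusion
(minutes–hours) and cell division (hours–tens of hours).  `d_g` is
stored in domain units, `d_g = D_G/(K_G L²)` with L the domain side;
the discrete solve uses lattice units, `d_g·(N−1)²`, so the GDNF
penetration depth into the mass, `√d_g·(N−1)` lattice sites, scales
with the grid and the dynamical regime is grid-size invariant.

**Cells.** Each step visits every cell present at the step start in a
fresh uniform permutation (cells created or moved during a sweep are
not revisited).  A cell with no empty von Neumann neighbour does
nothing.  Otherwise it proposes a move with probability `p_move`, else
a division.  Moves always execute; a division fires with probability
`Φ(c1 + c2·g)` evaluated at the mother's own grid point (or the flat
rate `p_const` when GDNF-stimulated division is toggled off).  The
destination among the K ≤ 4 empty neighbours is drawn from the softmax
`p_i = exp(β_a g_i)/Σ exp(β_a g_j)` with `β_move` for moves
(chemotaxis) and `β_div` for daughter placement (anisotropic cell
division); a disabled mechanism sets its β to 0, which reduces the
softmax exactly to the uniform choice.  Cell death is neglected, so
cell counts never decrease.  The field is re-solved once per sweep,
warm-started from the previous step.

The clamped boundary ring is treated like off-grid space by the
automaton — cells never move or divide onto it — which resolves the
otherwise ill-posed interaction between uptake and the Dirichlet
condition; masses are required to start (and in practice stay) well
inside the ring.  If an occupancy with cells on the ring is handed to
the field solver directly, the clamp wins and uptake is ignored there.

**Branching mechanism.** With `c1 < 0 < c2` cells divide only above the
switch midpoint `g = −c1/c2`.  The mass's own uptake screens the
interior, so division is confined to a rim layer; protrusions reach
into richer GDNF and divide faster, clefts are screened below the
midpoint and freeze.  This positive feedback is the entire branching
mechanism — there is no prepattern.

## Default parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `grid_size` | 120 | reference reduced-scale domain (experiments); 80 for the inference pilot library |
| `d_g` | 0.00075 | domain-unit diffusion coefficient; penetration ≈ 3.3 px at N=120 — see calibration note |
| `c1`, `c2` | −25, 120 | probit-switch location and sensitivity; midpoint g = 0.208 |
| `p_move` | 0.2 | probability a proposed action is a move |
| `β_move` | 20 | chemotaxis softmax sensitivity |
| `β_div` | 50 | anisotropic-division softmax sensitivity |
| `p_const` | 0.1 | division probability when the GDNF switch is off |
| `steps_per_hour` | 1.5 | CA sweeps per simulated hour |
| field tolerance | 1e-6 | diagonally scaled max-norm residual |
| `attachment_rule` | off | optional: reject moves whose destination has no occupied neighbour besides the mover's origin |

**Calibration note.** The defaults are the package's study conditions,
fixed once on the reference run and then frozen.  Two deserve comment.
First, `d_g`: under the published domain-unit value (0.006, tied to a
400×400 domain and an unpublished parameter table) the rim of any
admissible mass on a 120×120 domain sits at g ≈ 0.3–0.5, far above the
c2 = 120 switch midpoint, so division saturates and growth is compact
at this scale.  The reduced-scale default preserves the *dynamical
regime* instead of the literal number: with penetration ≈ 3.3 px the
rim operates at g ≈ 0.15–0.25, where the (−25, 120) switch
discriminates tips from clefts, a steep-midpoint switch (c2 = 400,
midpoint 0.063) saturates into compact growth, and a shallow one
(c2 = 20, midpoint 1.25) starves.  Second, the movement and timing
constants (`p_move`, the βs, `p_const`, `steps_per_hour`) are not
published; they were chosen so that a 30 h reference run grows several
fold and reaches branch counts in the high single digits, while
GDNF-independent control runs grow (≈3×) but stay compact.

## Morphometrics

Simulated rasters and experimental frames are processed identically.
`extract_bulk_mass` thresholds a grayscale frame (Otsu by default),
fills holes and keeps the largest 8-connected component.
`skeletonize_and_count` applies, for CA rasters
(`presmooth_radius` = 2): morphological closing with twice the radius
(the lattice mass is porous, and boundary *concavities* are the
dominant source of spurious junctions on a compact mass), hole
filling, opening with the radius itself (strips single-cell fuzz),
largest component, topology-preserving thinning, and trace-based
pruning of terminal spurs shorter than `spur_min_length` — by default
0.15× the raster side (18 px at N=120), because a compact mass's
medial-axis arms scale with its size, so no fixed pixel threshold is
scale-faithful.  A disconnected skeleton fragment shorter than the
threshold is removed as a spur itself; without this rule, pruning all
arms of a small central skeleton leaves an isolated junction clump
that always reads as one false branch point.  Branch points are
8-connected clusters of skeleton pixels with ≥ 3 skeleton neighbours;
each cluster counts once, whatever its degree.

Consequences to keep in mind: absolute branch counts carry a
method-dependent offset (pruning threshold, smoothing radius), so
cross-condition *orderings*, not absolute counts, are the meaningful
outputs; and pruning monotonicity (more pruning, never more branches)
is guaranteed on tree-like skeletons but can be violated by exotic
masks whose junction clusters split.

## AABC inference

Priors are independent uniforms: c1 ∈ [−40, −20], c2 ∈ [40, 280],
p_move ∈ [0, 1].  The pilot library holds m parameter triples drawn
from the prior, each simulated N = 2 times and summarised as
(normalised area, branch count) at t = 10, 20, 30 h.  For a proposal
θ*: distances to pilot thetas are Euclidean after rescaling each
parameter to unit prior range; the k nearest particles get Epanechnikov
weights `ω_i = (3/4)(1/d_(k+1))(1 − (d_i/d_(k+1))²)` and exactly zero
from the (k+1)-th onwards (rank ties broken by index; a selected
particle lying exactly at the bandwidth gets the smallest positive
kernel weight rather than zero).  A Dirichlet draw over the positive
weights sets resampling probabilities; each pseudo-replicate resamples
one whole replicate summary vector (particle from the Dirichlet draw,
replicate uniform).  Summary-space distance is between replicate means
after per-dimension standardisation by pilot-library standard
deviations (raw mode available); ε is set so the target fraction
(default 5%) of proposals is accepted, with ε reported as the smallest
distance strictly above the accepted set so that every accepted
distance < ε even under ties.

`k` trades kernel smoothing bias against variance.  The library default
is 50; the reduced-scale inference experiment uses k = 5 (1% of its
m = 500 pilot library) because at k = 50 the kernel radius spans about
half the scaled prior range and the pseudo-data smoothing flattens the
c2 signal into the prior marginal.

**Recovery experiment design.**  The c1–c2 pair is sloppy along the
midpoint ridge `c1 ≈ −0.2·c2`: parameter pairs on the ridge produce
nearly identical switches, so the data identify the ridge far better
than the position along it.  The reference truth for the recovery
experiment is therefore placed off the prior centre,
θ_true = (−30, 200, 0.2): there the identified ridge, intersected with
the prior box, pins c2 into a subrange and the posterior mean of c2 is
a meaningful estimate.  At a mid-prior truth the "posterior mean closer
than prior mean" comparison is powerless by construction — the prior
mean is already the optimum — which is a property of the experiment,
not of the inference machinery.

## Numerics

The field solve is successive over-relaxation for grids below 33,
otherwise a geometric multigrid V-cycle (damped Gauss–Seidel smoothing,
full-weighting restriction, bilinear prolongation, lattice coefficient
÷4 per level), warm-started from the previous step inside a simulation.
Convergence is judged on the fine grid by the max-norm of the discrete
residual divided by the stencil diagonal `4·d_g + [occupied]` (the raw
residual scales with `d_g` and would make a fixed tolerance
grid-size-dependent); the returned field is clipped to [0, 1], with any
excursion bounded by the tolerance.  Against a dense direct solve of
the assembled linear system the solver agrees elementwise to better
than 1e-8 at tolerance 1e-12.

All stochasticity flows from one seeded generator per simulation,
consumed in a fixed order (permutation, action uniforms, gate uniforms,
site uniforms per sweep), so trajectories are bit-reproducible across
runs and platforms.  Experiment batches derive per-replicate seeds from
a root `SeedSequence`.

## Synthetic data: what it does and does not emulate

The fixtures stand in for undeposited explant imaging: deterministic
initial masses (ellipse, ellipse-with-bud-lobes, cross) and observed
summary trajectories generated by the simulator itself at a known
truth.  They emulate the *structure* of the real data — a central
epithelial mass imaged over tens of hours, summarised as normalised
area and branch counts at a few time points, with replicate-to-replicate
variability — but not fluorescence noise, segmentation error,
mesenchymal influence, 3-D projection effects, or any discrepancy
between the CA model and real tissue.  Passing tests therefore show
that the pipeline is self-consistent and that the inference machinery
recovers what the model can identify; they cannot show that the model
is a faithful description of real explants.

## Problem sizes

Reduced-scale experiment sizes (the package's own choices): mechanism
ablation and switch sweep on the 120×120 grid with 50 replicates per
condition and a 30 h horizon; the inference experiment on an 80×80 grid
with an m = 500, N = 2 pilot library, 3 observed replicates and 2000
proposals.  Full-scale settings (larger grids, more replicates or
proposals) are one config change away via `RunConfig`.

## Known limitations

- Mesenchyme, the GDNF–Wnt11–RET feedback loop, mechanical forces,
  cell death and 3-D geometry are outside the model by construction.
- Absolute branch counts depend on the morphometric settings; only
  orderings across conditions are calibrated.
- The c2 marginal is identified mainly through the midpoint ridge;
  steepness per se is weakly informative at these summary statistics.
- The attachment-rule variant implements the cheapest local reading of
  "stay attached to at least one neighbour" (destination support check);
  global connectivity of the mass is not enforced.
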