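# Methods

## Model

The tissue is a simply connected planar tessellation with a free boundary:
cells are counterclockwise polygons over a shared vertex set, edges are
derived from the cell cycles (never stored separately), and the Euler
relation `V − E + N = 1` is an invariant that every topological event must
preserve.  The energy of cell *i* is

    E_i = η_i (A_i − A0)² + μ_i P_i² + σ_i Σ_j (l_ij − l0)² + ϕ_i Σ_j (α_ij − α0)²

with the regular hexagon of edge `l0` as reference (`A0 = (3√3/2) l0²`,
`α0 = π/3`).  All quantities are dimensionless; lengths are in units of
`l0`.  Coefficients are stored per cell so chemo-mechanical coupling needs
no special-casing; uniform tissues replicate one value.

Angle semantics.  `α_ij` is the signed turning (exterior) angle at vertex
*j*, from the 2-argument arctangent of the cross and dot products of the
incoming and outgoing edge vectors.  This is the only reading consistent
with all of: `α0 = π/3` for the regular hexagon, a quadratic penalty that
is minimized by the reference shape, and the existence of "negative
angles" at concave vertices when `ϕ = 0`.  An unsigned (arccos) angle
would make convex and reflex vertices indistinguishable.  The angles of a
simple counterclockwise polygon sum to `2π` exactly, which the tests use
as a geometric invariant.

Forces are the negative analytic gradient of the total energy,
term-by-term: the shoelace-area gradient, unit-edge-vector differences for
the perimeter and edge terms, and the gradient of the atan2-based turning
angle (each angle touches three vertices; the three contributions sum to
zero, which makes the energy exactly translation- and rotation-invariant).
A central finite-difference oracle (`finite_difference_forces`) is kept in
the package as an independent check; the test suite requires agreement to
better than 1e-5 relative on randomly perturbed patches with all four
terms active.

Dynamics are first-order (overdamped) with a yield threshold:
`V = k F H(|F| − F0)`, explicit Euler at `Δt = 0.005`, `k = 0.5`,
`F0 = 0.1`.  `H` is inclusive at zero (`|F| = F0` does not move), gating
is on the vector norm, and boundary vertices obey the same rule as
interior ones (free boundary).  All forces are evaluated at the start of
the step and all positions updated together, so results are independent
of vertex ordering.

## Events

Division: probability `p_div = p0 q^(n0−6)` per cell per time step
(`p0 = 5e-5`, `q = 1.4`); each existing cell draws one uniform variate
per step in cell-id order from a single seeded RNG stream — the only
randomness in a run.  The longest edge (ties: lowest in-cycle index) and
its opposite (antipodal edge for even `n0`; the longer of the two edges
flanking the antipodal vertex for odd) are bisected, the midpoints joined,
and the neighbors sharing the split edges each gain one side.  The mother
keeps its cell id; the daughter is appended at the end of the list and
inherits the mother's instantaneous concentrations and coefficients.

Intercalation: interior edges shorter than `d_int = 0.15` are processed
shortest-first each step; a T1 swap requires the generic configuration
(two incident cells, valence-3 endpoints) and is rejected if any incident
cell would drop below four sides.  The rotated edge is placed
perpendicular about the old midpoint with length
`post_length_factor · min(d_int, old length)` (`post_length_factor = 1.5`):
proportional to `d_int` in the generic case so the new junction is not
immediately re-eligible, but capped at the local scale so a swap deep
inside a strongly contracted region cannot stab across neighboring cells.

Chemistry: `dC_i/dt = Σ_j δ l_ij (C_j − C_i) − β C_i` (`δ = 1`,
`β = 0.04`), explicit Euler synchronized with the mechanics, flux through
each shared edge proportional to its length.  The sign is fixed so that a
cell richer than its neighbors loses mass; with `β = 0` and no source the
update conserves total concentration to round-off and obeys a discrete
maximum principle at this `Δt`.  Source cells (centroid within a band of
the left boundary, default width 1.5 `l0`) are clamped to `C_src = 1`
after each update.  Coupling is linear with clamping,
`coeff_i = clamp(−k1 |C_i| + b1)`; the defaults `k1 = 1/C_src`, `b1 = 1`
drive `ϕ → 0` at the source (shape-flexible cells) and `ϕ → 1` far away.

Step order within one `Δt`: mechanics → chemistry → coupling → divisions
→ intercalations → repair (below).  The order is a convention (the
mechanics and chemistry are synchronized; events are rare on the step
scale) and is fixed for reproducibility.

## Numerical safeguards

Two guards keep the explicit integrator inside its stability region in
the strongly contracting parameter regimes, where cells legitimately
shrink far below the reference scale and the angle-term stiffness (which
scales as `1/l²`) outruns any fixed time step:

- Displacement cap: no vertex moves further in one step than
  `max_step_frac = 0.25` of its shortest incident edge.  Inactive in all
  uniform-regime runs (displacements there are orders of magnitude
  smaller); it only engages where the raw update would already be outside
  the Euler stability limit and would invert a polygon within one step.
- Degenerate-edge repair: edges shorter than `repair_min_edge = 0.02 l0`
  — far below `d_int`, typically boundary edges or non-generic junctions
  that intercalation cannot legally remove — are collapsed by merging
  their endpoints (one vertex and one edge removed, Euler relation
  preserved, guarded at `n0 ≥ 4`).

Both are config-exposed and can be disabled.  If the mesh still leaves
the space of valid tessellations (non-finite state, non-positive cell
area at a sample, final integrity failure), the run halts and is labeled
`unstable` — a reported outcome, not an exception.  This is the observed
fate of the fully compressible bubble pair (μ = 1.0, η = 0.1, σ = 0):
with no edge elasticity, contraction is unbounded (the energy minimum is
total collapse, and the force threshold would arrest it only near 1% of
the reference scale), cells pass through zero area, and the tessellation
tangles.

## Observables and regime classification

Per-sample records (default cadence: every 100 steps) hold `N`, `U/N`,
polygon-class fractions `P_n` over {4, 5, 6, 7, 8+}, class-wise mean
areas `⟨A_n⟩/A0` (absent classes are missing, not zero), the pooled
`⟨A_{n≥5}⟩/A0`, the all-cells mean side count `⟨n⟩` and mean unique-edge
length.  Steady values are trailing means over the last 20% of samples:
growth never halts (divisions continue at the target size), so a strict
stationarity stop on `P_n` is ill-posed and is provided only as an
optional gate (`steady_pn_tol`).

`⟨n⟩` over all cells of a bounded conforming tessellation is pinned near
six by Euler's relation (interior-only averaging tends to exactly six as
the patch grows, which the tests verify on 3-, 5- and 7-ring patches);
boundary cells pull the all-cells mean slightly below six.  An
adjacency-weighted variant (`mean_sides(..., weighting="neighbors")`),
which samples cells in proportion to their neighbor count and is biased
above the plain mean, is provided as well; reported grown-tissue values
use the all-cells mean.

Regime labels operationalize the phase-diagram regions.  The primary
split is the mean geometric scale: a tissue whose mean edge length
(< 0.35 `l0`) and mean area (< 0.15 `A0`) have both collapsed is in one
of the two collapsed states; there, the class-area disparity
`⟨A_{n≥7}⟩/⟨A_4⟩` separates the bubble state (large many-sided cells
among contracted quadrilaterals; class-area ratios near 4, against
roughly 2.3 for uniform tissue, so the default threshold is 3) from the
thread state.  An uncollapsed tissue is uniform unless one
many-sided cell dominates the area distribution (more than three times
the median).  The steady `U/N` and the undeformed-lattice line `μ(6l0)²`
are recorded as diagnostic scores: at mild contractility the uniform
state holds `U/N` above that line and the collapsed states below it.
All thresholds live in `RegimeThresholds`.  At the desk scales used here
the moderately contracted bubble states (e.g. μ = 0.5 with small η,
σ = 1) are geometrically close to the η = 0 thread state (both collapse
to a linear scale near 0.29 with measured disparities 2.5–2.9 straddling
the threshold), so labels near that boundary are sensitive and should be
read with their scores; the strongly contractile bubble states (μ ≈ 0.9)
separate cleanly (disparity 3.5–4.4).

## Study conditions and problem sizes

Runs grow a 32-cell defect-free hexagonal patch (the single-hexagon
initial condition is also provided) to a 500-cell target under the fixed
parameter set (`k = 0.5`, `F0 = 0.1`, `p0 = 5e-5`, `q = 1.4`,
`d_int = 0.15`, `δ = 1`, `β = 0.04`, `Δt = 0.005`), ~55 000 steps, with
three seeds per condition; this is the package's chosen desk scale for
steady statistics.  The test suite uses the same conditions with the
phase sweep scaled to 150-cell targets.  What passing tests show: the
mechanics is an exact gradient flow of the stated energy, events preserve
the tessellation invariants, the chemistry is conservative and
monotone, and the emergent polygon-class structure (modal hexagons,
graded class areas, energy ordering across regimes) is reproduced.  What
they do not show: agreement with tissue statistics at 2000–10⁴ cells,
exact phase-boundary locations, or absolute cell-area scales in the
contraction-dominated regimes, where the simulated tissue relaxes to a
deeper contraction equilibrium than reference snapshots of such tissues
show (the relative class-area structure matches; the absolute anchor
does not — see the discussion of limitations below).

## Known limitations

- The model has no excluded volume: nothing prevents a cell from passing
  through zero area when contraction is unbounded (σ = 0 with large μ).
  Such runs end `unstable` by design.
- Division probability depends only on side count, not cell size or age;
  at collapsed scales tiny cells keep dividing.
- The bubble/thread boundary of the classifier is heuristic and
  scale-dependent; labels near the phase boundary should be read together
  with their diagnostic scores.
- Mean side counts above six, as sometimes quoted for grown epithelia,
  are not achievable for a conforming bounded tessellation with
  valence-3 interior vertices; this package reports the Euler-consistent
  all-cells mean and offers the adjacency-weighted variant.
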