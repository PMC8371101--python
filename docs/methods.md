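# Methods notes

These notes document the modelling and numerical choices behind `alveonet`,
in the spirit of a model-description appendix: what is simulated, under
which assumptions, which knobs matter, and what the implementation does at
the points where the design was genuinely open.

## 1. Network geometry

Fibers are straight chords of the unit square: `n` anchor points uniform on
[0,1]², one angle per fiber uniform on [0, 2π), each chord extended to the
boundary.  All waviness is carried by rest lengths, never by curved
geometry.  Cross-linking is a single Bernoulli(ρ) draw per fiber–fiber
crossing; a bonded crossing becomes a degree-4 node shared by the four
half-fibers, an unbonded crossing leaves the two fibers free to pass
through one another (no contact forces).  The perimeter is covered with
elastin-typed "edge" springs between consecutive boundary nodes, so the
frame itself is elastic.  Networks are therefore regular in the sense that
every interior node has degree exactly 4; there is no branching.

Degree accounting: the headline *mean connectivity degree* is the total
degree of bonded nodes divided by the number of crossing sites (bonded or
not), which equals 4ρ in expectation — 3.4 at the baseline ρ = 0.85.
Averaging over existing nodes only would give exactly 4 for any ρ > 0 and
carry no information about cross-linking; both variants are available in
`average_degree`.

Geometric tolerances: candidate node points closer than 10⁻⁹ are merged
(zero-length-segment protection); chord pairs with |sin Δθ| < 10⁻¹² are
treated as non-intersecting (a measure-zero, numerically unstable case).
Fiber endpoints landing on a corner reuse the corner node.

Reproducibility: each realisation uses one `numpy` PCG64 stream seeded from
its config; draws occur in a fixed order (anchors, angles, fiber types,
bonds, isotropising factors, w₁, per-segment waviness), so a (config, seed)
pair maps to a byte-identical serialised network.

## 2. Constitutive initialisation

Two-phase scheme:

1. **Isotropising pass.**  Every segment gets `r₀ = geometric length ×
   U(0,1)` and `k = 1/r₀` (unit stiffness `k·r₀ = 1`).  All springs are
   then at or under tension, and relaxing the network produces a
   disordered, approximately isotropic reference geometry that has
   forgotten the straight-chord construction.  During this relaxation all
   four edges are held co-linear (boundary nodes slide along their own
   edge).  This boundary choice is deliberate: if only the left/right
   edges are pinned here, the specimen necks at baseline, the reference
   configuration collapses inward, and collagen recruitment during stretch
   is systematically inflated (mean recruitment at first percolation rises
   from ≈0.40 to ≈0.54 in healthy ensembles).  The spread, frame-pinned
   reference also matches how the initial configurations of such models
   are conventionally depicted.

2. **Final pass**, from the relaxed equilibrium lengths `L`:
   * elastin: `r₀ = L`, `k = 1/r₀` — at rest in the reference state, so
     elastin elongates (and bears load) from the first increment;
   * edge: `r₀ = 0.95 L`, `k = 1/r₀` — the frame is pre-tensioned;
   * collagen: `r₀ = w·L` with waviness `w` drawn per segment from a beta
     law on `[w₁, w₁+0.65]` with shapes a = 1.89, b = 3.6 (an empirical
     alveolar-collagen waviness distribution; the density vanishes at both
     endpoints).  Collagen is thus slack at baseline and recruits only
     once its end-to-end distance exceeds `w` times its reference length.

**Collagen stiffness.**  `k` is re-initialised as `1/r₀` and multiplied by
a waviness-dependent factor with a flipped-Burr profile (c = 1, κ = 10):
wavier fibers are rarer but much stiffer, which emulates crimp formation
(stiffer fibers buckle into deeper waves).  The factor is normalised so its
maximum (at `w = w₂`) equals the amplification γ exactly: with γ = 10³ the
stiffest collagen is 1000-fold stiffer than unit-stiffness elastin, and the
least wavy collagen about 250-fold softer than that.  Using the raw Burr
*density* value as the factor instead (available as `burr_raw=True`) would
carry the density's amplitude c·κ and make the stiffest collagen γ·c·κ =
10⁴-fold stiffer; the normalised form is the default because the
collagen:elastin stiffness contrast of the model is specified as three
orders of magnitude, not four.  A `k_mode="replace"` switch sets
`k = factor` without the `1/r₀` composition, for sensitivity analyses.

**Condition presets.**  healthy: γ = 10³, w₁ ~ U[1.3, 1.4]; mild fibrosis:
γ = 10⁴ (stiffer collagen only); severe fibrosis: γ = 10⁴ and w₁ ~
U[1.1, 1.3] (stiffer *and* less wavy, with a wider between-realisation
spread emulating patient heterogeneity).  w₁ is drawn once per network;
w₂ − w₁ = 0.65 always.

**Collagen fraction α.**  The fraction of fibers that are collagen is not
well constrained by measurement and defaults to 0.5.  Two observations
support this placeholder: the bond-percolation threshold of the collagen
subnetwork at α = 0.5 lands at 0.72 for 480-fiber, ρ = 0.85 networks
(section 4), and lung-parenchyma collagen:elastin mass ratios bracket it.
All results depend on α; it is exposed everywhere.

## 3. Mechanics and the solver

Energy is the sum of `½k(d−r₀)²` over segments, with the slack clause
zeroing both energy and force of unrecruited collagen; the landscape is C¹
(forces vanish continuously at `d = r₀`) but not C².  Elastin and edge
springs resist compression with the same Hookean law.  Bending stiffness,
dynamics, viscoelasticity and bond breakage are all outside the model.

Uniaxial stretch fixes left-edge abscissae at 0 and right-edge abscissae at
`1 + ε`, ordinates free (co-linear edges); top/bottom and interior nodes
are fully free, so the sample necks.  The strain grid is 0 to 1 in steps of
0.05 (21 states).  Each step warm-starts from the previous equilibrium with
all x-coordinates scaled by the width ratio (an affine guess that roughly
halves solver iterations relative to shifting the right edge alone) and
minimises the energy over free coordinates.

The minimiser is an own L-BFGS (memory 20, two-loop recursion, Armijo
backtracking) compiled with numba, with a diagonal inverse-Hessian seed
`1/Σ(incident k)` per node.  The preconditioning matters: spring constants
span ~5 orders of magnitude once collagen is amplified, and the seed cuts
iteration counts several-fold.  Convergence is declared when the net
*spring* force on every free node is ≤ 10⁻² (per-node Euclidean norm, the
model's force threshold); the evaluation cap is 5·10⁴ per stretch step
(2·10⁵ for the initial relaxation), and a step that fails the threshold is
recorded as unconverged (a warning, never an exception) while the protocol
continues.  A scipy `L-BFGS-B` route is kept behind `method="scipy"` as an
independent cross-check; the test suite verifies both routes against
closed-form two-spring equilibria and against each other on convex
(collagen-free) networks.  Tightening the tolerance to 10⁻³ changes neither
percolation strains nor recruitment readouts in spot checks.

Nodes attached only to slack collagen have no unique minimiser ("floppy"
nodes); any zero-gradient position is accepted.  An optional quadratic
tether (weight 10⁻⁸, off by default) anchors free coordinates at their
warm-start values as a conditioning aid; it is excluded from the residual
criterion and verified to change the boundary force by less than 10⁻⁴
relative.

Stress is nominal: boundary force divided by the undeformed right-edge
cross-section (length 1 × unit thickness), so stress equals force in model
units.  Dividing by the current necked edge height instead is available
behind `area_mode="current"`; cross-condition comparisons normalise forces
to the healthy mean at strain 1, so the choice does not affect them.

## 4. Percolation

*Mechanical*: after each converged step, the subgraph of recruited collagen
segments (`d > r₀`, strictly) is tested for a connected component touching
both the left and right boundaries.  Connectivity is purely topological
(shared bonded nodes); elastin and edge segments never enter the subgraph,
though they transmit the forces that cause recruitment.  The implementation
labels components with `scipy.sparse.csgraph` and extracts a witness path
by breadth-first search; tests compare against independent BFS and
union-find oracles.

*Bond*: segments of the collagen subnetwork are occupied independently with
probability p; the observable is the largest set of occupied segments
mutually connected through shared nodes, as a fraction of eligible
segments, averaged over an ensemble, on a p-grid of step 10⁻³.  The sweep
uses coupled sampling: one uniform mark per segment, so the occupied set at
probability p is exactly the marks ≤ p and a single sorted union-find pass
yields the whole curve per network.  Marginally each p is an independent
Bernoulli(p) occupation, so the ensemble mean is identical to re-drawing at
every p, at a tiny fraction of the cost.  The threshold is the abscissa of
the steepest ascent of the ensemble-mean curve after a centred moving
average (window 21 grid points ≈ 0.021 in p; raw Monte-Carlo curves are too
noisy for a pointwise derivative argmax), excluding the half-window margins.

Occupying the *whole* fiber lattice instead (`eligible="fiber"`) puts the
transition near 0.5 — the classic bond-percolation point of a degree-4
planar lattice — because occupying segments connected through shared nodes
is bond percolation on the node graph.  The elastin dilution of the
collagen subnetwork is what pushes the threshold up to ≈0.72 at α = 0.5,
ρ = 0.85, with an approximately linear dependence on ρ (0.61 at ρ = 0.2 to
0.75 at ρ = 1).

## 5. Ensembles, sweeps, scale

Replicate seeds derive from `SeedSequence([master, index, attempt])`; a
degenerate realisation (no collagen segments, no crossings — possible only
at tiny n or extreme α) is replaced by a fresh seed up to 5 attempts, with
a log record.  Confidence bands on mean stress are symmetric normal
approximations at level 0.99 by default (a bootstrap option exists).
Normalisation divides all stresses by the healthy-condition ensemble mean
at strain 1 and is idempotent.

Desk-scale defaults — 50 stretch replicates per condition, 200 networks for
bond percolation, 16 replicates per sweep cell — keep a full analysis in
the minutes range on one CPU; the full-scale counts (3000 replicates, 4000
networks, 40 per cell) are reachable purely through configuration, with
identical code paths.  Problem sizes used by `scripts/acceptance.py`: 200
networks (480 fibers) for the threshold, 200 baseline networks for the
degree, 24 healthy stretch replicates for recruitment-at-percolation, 100
networks per ρ for the ρ sweep, 16 replicates per elastin scale.

The elastin sweep multiplies all non-collagen spring constants (elastin and
edge) by a scalar in [10⁻³, 10³] after the constitutive pass; baseline 1.
Because mean recruitment in this model rises monotonically all the way to
100% strain at every scale, the "strain of peak recruitment" is degenerate
(always the last grid point); the sweep is instead summarised by the
*half-rise strain* — the interpolated strain at which a scale's mean
recruitment first crosses half the sweep-wide maximum.  An
earlier-developing recruitment curve gives a smaller value.  Because the
half-rise profile over the log-spaced scale grid is a shallow basin whose
pointwise argmin is noise-dominated, the sweep's optimum is located by
fitting a parabola to the profile in log₁₀(scale) and taking the vertex
(`SweepResult.optimum_scale`); the discrete argmin remains available.

## 6. What the generator does and does not emulate

The synthetic networks emulate: random, isotropic, web-like fiber
architecture; permanent inter-fiber cross-linking at tunable density; the
measured waviness distribution of alveolar collagen; the ~10³ stiffness
contrast between collagen and elastin; heterogeneity between tissue
samples (per-network w₁).  They do not emulate: fiber branching (all
interior nodes are degree 4), curved or extensible-contour fibers, 3D wall
thickness, strain-stiffening fiber laws, transient/breakable bonds
(viscoelasticity), cellular components, or spatial correlations in fiber
placement.  Passing tests therefore certify the model's internal mechanics
and statistics, not fidelity to any particular tissue specimen.

## 7. Known limitations and open quantitative gaps

* Mean collagen recruitment at the first mechanically percolating strain
  comes out ≈0.40 in healthy desk-scale ensembles (α = 0.5), above the
  0.20–0.30 band this class of model is associated with; the gap shrinks
  only at collagen fractions near 0.8, for which there is no independent
  support.  The qualitative contrast that matters — mechanical percolation
  engages at recruitment far below the ≈0.72 random-occupation threshold —
  is robust in all conditions tested.
* The half-rise strain of the elastin sweep is statistically flat across
  scales 0.1–10 at feasible replicate counts (differences ~0.01 strain), so
  the located "optimal" scale wanders within that decade around baseline;
  the model does not sharply single out the baseline scale, because its
  recruitment curves never develop the interior peak that would separate
  stiff-elastin behaviour.
* Mechanical percolation strains in healthy ensembles concentrate at
  0.55–0.85, i.e. 15–45% strain beyond the maximum minimum-waviness (1.4),
  somewhat later than the ≈10%-beyond rule this model family suggests.
* Finite-size effects: at n = 48 a single realisation's stress curve is
  dominated by a handful of percolating chains; condition comparisons are
  only meaningful as ensemble means.
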