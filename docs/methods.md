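# Methods

## The model

`viadeco` analyses deterministic cell models of the form x' = f(x) on R^n
together with a *viability region* V = {x : g_i(x) <= 0 for all i} — the
set of states in which the cell counts as alive. Constraints are
per-variable bounds (an essential variable with a lower and/or upper
threshold) or smooth scalar functions. The region is closed: boundary
states are members, and death occurs at the first transversal crossing.
The literature does not settle whether the boundary itself is alive; we
adopt the closed convention uniformly and every operation documents it.

A state is

* **asymptotically viable** if its forward trajectory stays in V and
  converges to a stable attractor inside V,
* **transiently viable** if the trajectory leaves V in finite time (the
  *death time*, with the violated constraint recorded),
* a **nonmember** if it starts outside V,
* **undecided** if the simulation horizon is reached first. Undecided is a
  first-class outcome: a finite-horizon simulation never silently reports
  survival.

`classify_state` implements this by event-driven integration and is the
brute-force oracle against which every geometric structure below is
verified.

## Organizing manifolds

Three families of backward-time curves decompose V by survival outcome:

* **Mortality manifolds.** Where the flow is tangent to a facet of the
  boundary (the normal component f·n vanishes), the boundary flow switches
  between immediately fatal and inward. If the tangency's forward fate is
  asymptotically viable it is a *mortality point*, and its backward-time
  trajectory separates the asymptotically viable set from the transiently
  viable one. Tangencies whose forward fate is transient are retained but
  marked non-organizing.
* **Ordering manifolds.** A corner where two constraints meet and the flow
  exits through both facets at once is *jointly fatal*: trajectories
  reaching it kill both cells simultaneously. Its backward-time trajectory
  separates initial conditions by which constraint is violated first.
  Corners with a vanishing normal component are reported in a marginal
  list and not seeded; intersections of three or more constraints are
  detected and reported but not seeded.
* **Collapse manifolds.** In a multicellular system, a state on a dying
  cell's death facet whose projection lands exactly on an organizing
  structure of the survivors' reduced dynamics (here: an unstable
  equilibrium) extends backward into the pre-death space, separating
  initial conditions by the survivor's post-collapse fate. Stable-attractor
  preimages are valid facet states but flagged non-organizing and refuse
  to seed a manifold. General separatrix targets can be supplied as
  registered points; only equilibrium targets are auto-classified.

Exact polyline computation is restricted to two-dimensional state spaces,
where the backward trajectory of a point is itself the codimension-1
object. In higher dimensions the probe-classification oracle
(`verify_separation`) remains available, but no globalization of
(n−1)-dimensional manifolds is attempted.

Every manifold is checkable rather than trusted: `verify_separation`
samples the polyline uniformly in arclength (seeded RNG), places probe
pairs at ±band along the local normal, classifies both probes with the
brute-force oracle and reports the fraction of pairs that land on the
advertised sides. Probes outside the region or within one band of the
boundary are skipped and counted. Fraction 1.0 is the definitional
property of a correct manifold, and is what the acceptance checks assert.

## The hybrid multicellular system

Cells own disjoint sets of state variables, each with its own viability
region. The group evolves under the dynamics registered for the current
alive subset; when one or more constraints cross (within a simultaneity
tolerance `tie_tol` = 1e-9 time units, so corner hits are detectable
despite being measure-zero), the crossing cells die, the state is mapped
by the collapse rule, and integration continues in the reduced space.
Dynamics are supplied per alive subset explicitly because post-death
dynamics are not in general a restriction of the full field. The default
collapse rule is coordinate projection (survivors' coordinates preserved
bit-identically); a custom rule may append inert debris variables.

A start outside some cell's region is an event at t = 0, not an error, so
batch sweeps over initial conditions are total.

The possible alive subsets form the *configuration graph*: all 2^k subsets
as nodes and an edge for every (source, nonempty dying subset) pair —
sum over subsets S of (2^|S| − 1) = 3^k − 2^k death events for k cells
(19 for k = 3). Simulations flag the edges they take; realized edges are
always a subgraph of the possible ones.

## Intrinsic viability of the glider

The continuous modules impose viability from outside. The Game-of-Life
module derives it from within: a glider persists exactly as long as the
update rule (birth on 3 live Moore neighbours, survival on 2 or 3,
synchronous, quiescent exterior) keeps regenerating its pattern. The
individual is one chirality/heading of the glider: four phase patterns of
five cells each plus their one-cell-thick off membrane, which belongs to
the individual — windowed matching requires the membrane to be entirely
off. Re-identification across rotations/reflections is off by default (a
modeling choice: the glider is a single individual).

A glider-environment configuration is classified by exhaustive simulation:
*nonmember* if no glider is present at t = 0 (the complement of the viable
set is every configuration not containing the glider — this includes a
glider with a cell removed), *interior* if the identity is re-found at
every period-4 checkpoint up to the horizon (default 64 steps), *boundary*
if the identity is lost and never regained — only a terminal loss counts,
so loss-then-recovery is interior with a `recovered` flag. Perturbation
windows default to a rectangle ahead of the glider's heading, where
collisions occur; the window is reported with every result because the
extent of "the environment" is a parameter, not a fact.

The engine is a convolution over a bounded window that grows by 8 cells
per side when live cells reach its edge (capped at 512×512, then a
`WindowOverflow`). It is cross-validated cell-for-cell against an
independently coded double-loop update on seeded random soups.

## Fixtures

The schematic phase portraits are instantiated as concrete systems with
closed-form-verifiable facts:

* **Scenario A** — linear sink at (0.5, 0.5) in [0, 1]^2; all boundary flow
  inward; every interior state asymptotically viable.
* **Scenario B** — the sink moved to (1.5, 0.5): every interior state exits
  through the upper x1 facet; from the center the death time is exactly
  ln 2.
* **Scenario C** — stable spiral (decay λ = −0.1, rotation ω = 1) at the
  origin in [−1, 1] × [−1, 0.5]. The flow is tangent to the upper facet at
  ω x1 + λ x2 = 0, i.e. (0.05, 0.5); that tangency is the unique
  organizing one (the spiral grazes every facet once, but only this
  tangency's forward fate is asymptotic), and its mortality manifold
  splits the box into survivors and casualties.
* **Two-cell system** — "blue" and "purple", one essential variable each
  with lower bounds b_min = 0.1, p_min = 0.05. Joint dynamics is the
  triangular linear field b' = −α(b − c_b) − κ(p − c_p),
  p' = −γ(p − c_p) with α = 1, γ = 1.4, κ = 0.3, c_b = −0.3, c_p = −0.2:
  coupled, drives both variables below their thresholds (so the corner is
  jointly fatal), and linear so every fact has a closed form. Each
  survivor's solo dynamics is the bistable cubic x' = −x(x − a)(x − 1)
  with a = 0.4: viable attractor 1, unstable point a, terminal attractor 0
  below the threshold. The collapse point is (a, p_min) exactly.

Fixture constructors are deterministic and their expected facts are
re-verified by the test suite using the package's own operations — the
fixtures cannot drift away from what the algorithms actually find.

What the fixtures do **not** emulate: high-dimensional state spaces,
non-box viability boundaries with curvature, stiff or non-smooth dynamics,
stochastic death hazards, birth events, and spatial/mechanical coupling.
Passing tests demonstrate the geometry and the algorithms on systems where
ground truth is analytic; they do not certify behaviour on real cell
models with those features.

## Numerical choices

* Integrator: adaptive Runge–Kutta (RK45) with dense output,
  rtol = 1e-8, atol = 1e-10. Backward trajectories amplify local error,
  and manifold geometry is sensitive to drift, so defaults sit well below
  the fixtures' geometric scales.
* Backward integration negates the right-hand side (uniform contract);
  backward trajectory times are reported nonpositive and decreasing.
* Boundary events fire on the viable-to-violated crossing (g through 0
  from below) and are refined by the integrator's event root-finding.
  Manifold seeds lie on the boundary, so backward runs start from a 1e-9
  inward nudge (the seed itself is kept as the polyline's first point).
* Backward manifold runs halt at region exit; in directions where the
  region is unbounded they halt at seed ± 2.0 (an analysis window, flagged
  `window_exit`, not a model constraint), and at ||f|| < 1e-12 when they
  run into an interior equilibrium (flagged).
* Tangencies are bracketed on a facet scan (default 256 samples) and
  refined by Brent root-finding to 1e-10; doubling the scan resolution
  finds nothing new on the fixture facets.
* Finite-difference Jacobian fallback: central differences with step
  h = 1e-6 · max(1, ‖x‖).
* Equilibrium search: multistart quasi-Newton from a seeded scrambled
  Sobol sequence, roots merged within 1e-6. Multistart search is
  documented as potentially incomplete.
* Convergence declaration: a trajectory is asymptotically viable when it
  comes within conv_tol = 1e-2 of a stable attractor that has more than
  conv_tol clearance from the boundary. For the fixtures this is safe
  (the linear sinks and the spiral have monotonically decreasing distance
  to the attractor), and it keeps scenario C decidable inside the default
  horizon of 50 time units (the spiral decays at rate 0.1, so reaching a
  1e-2 ball takes ≈ ln(0.5/0.01)/0.1 ≈ 39 time units).
* Grid classification uses cell centers (strictly interior by
  construction) and additionally skips points within 1e-9 of the boundary
  to avoid event-at-start ambiguity.
* Artifact reproducibility: all floats are written at 12 significant
  digits, all randomness flows from one seed, and identical run
  configurations produce byte-identical CSV/JSON/DOT artifacts.

## Problem sizes

The shipped analyses use 20×20 classification grids, 100 separation
probes per manifold, 50-trajectory hybrid batches, a 64-step glider
horizon and single-flip 3×3 perturbation windows. These sizes were chosen
so that every expected fact is exercised with comfortable margins while a
full reproduction stays in the tens of seconds; all of them are plain
function arguments and can be scaled up freely.

## Known limitations

* Exact manifolds only in 2-D; no continuation of higher-dimensional
  manifolds and no tracking of manifold bifurcations.
* Multistart equilibrium finding can miss roots; supply analytic
  equilibria where known.
* The hybrid simulator assumes each alive subset's field is registered
  explicitly; no automatic reduction is derived from the full field.
* A single-flip perturbation placed away from the glider's membrane dies
  in one step (an isolated live cell has no neighbours) and therefore
  cannot perturb the glider — partitions over distant windows are
  legitimately all-interior. Non-trivial boundary cases need either
  multi-cell flips or persistent structures (e.g. the glider-vs-block
  fixture, which disintegrates at step 20).
* Death is deterministic and instantaneous; probabilistic hazards,
  time-varying constraints and birth/division events are out of scope.
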