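# Methods

## Model

The extracellular matrix of lung parenchyma is modeled as a planar
network of linear springs: the ridge segments of a Voronoi tessellation
of uniformly random seed points in a rectangle. Each spring `i` carries a
rest length `L0_i`, a cross-sectional area `csa_i` (dimensionless,
homeostatic value 1) and a stiffness `K_i = k0·csa_i` — stiffness is
strictly proportional to csa, expressing that collagen molecules share
one Young's modulus and fiber stiffness counts molecules in parallel.
Elastic energy is `Σ ½·K_i·(L_i − L0_i)²`; springs support compression
with the same quadratic law (no buckling model). The outer rim of the
clipped tessellation is pinned at positions corresponding to a uniform
biaxial pre-stretch, so the tissue is under tension at rest.

Fibroblasts are agents performing unbiased random walks on the network:
at each step an agent picks one incident spring uniformly at random,
evaluates that spring's strain `ε = (L − L0)/L0` and stiffness `K`, and
computes its activation

    a = w1·a_ε(ε) + w2·a_K(K) − c ,

with `a_ε`, `a_K` Hill functions (`a_x(v) = amp·vⁿ/(v50ⁿ + vⁿ)`) and
`c = w1·a_ε(ε_home) + w2·a_K(k0)`, so that activation vanishes exactly
at the homeostatic set point (`ε = ε_home`, `csa = 1`). The agent then
updates the spring multiplicatively, `csa ← csa·(1 + δ·a)`, clamped to
`[csa_min, csa_max]`, and moves to the opposite node. The evaluation
happens before the update, and the update before the move. One
*iteration* = every agent steps once, then the network is re-solved for
mechanical equilibrium. Negative strain (transient compression) is
clamped to zero before entering the Hill function, whose argument must
be nonnegative.

Two feedbacks coexist. Strain sensing is homeostatic: springs strained
above `ε_home` are stiffened (which lowers their strain) and springs
below are digested — self-healing. Stiffness sensing is profibrotic:
stiff springs are stiffened further. The stiffness `K*` solving
`a(ε=0, K*) = 0` is the *fibrotic threshold*: springs stiffer than `K*`
deposit even at zero strain and are locked into fibrosis. `K*` is
emergent from the parameters (a helper, `fibrotic_threshold_stiffness`,
computes it by bracketing); with the shipped defaults `K* ≈ 5.5·k0`,
just above the injury level.

## Injury protocols (synthetic-data generator)

Injuries emulate an instantaneous insult (e.g. local inflammation) at a
configurable iteration: selected springs have their csa set from 1 to an
injured value (default 5). Three generators are provided:

- `random_injury`: `round(fraction·N)` springs chosen uniformly without
  replacement (defaults: fraction 0.2, csa 5). Rounding is
  round-half-even for cross-platform determinism.
- `clustered_injury`: a single connected cluster grown by breadth-first
  accretion from a seed spring, frontier visited in ascending spring id
  (reproducible tie-break). The target cluster size is a parameter.
- `modify_spring`: copy of a pattern with exactly one assignment
  changed, with provenance — the building block of hotspot sweeps.
  "Removing" a spring is expressed as modifying it to the csa floor, not
  topological deletion, preserving mesh validity.

What the generator emulates: the injured-fraction, injured-csa and
injury-timing protocol of a sudden insult on homeostatic tissue, and the
spatial statistics of random or clustered damage. What it does not
emulate: gradual (days-to-weeks) injury accrual, inflammatory cell
dynamics, multiple insults, or any image-derived injury geometry.
Passing tests therefore speak to the model's internal dynamics under
idealized injuries, not to prediction on clinical images.

## Network construction choices

The raw clipped tessellation is unsuitable as a mechanical substrate in
two ways, both repaired at generation time (and both switchable off):

1. Near-degenerate Voronoi ridges (length → 0) turn any nodal
   displacement into enormous strain; ridges shorter than
   `min_edge_frac` (default 0.25) times the mean length are contracted.
   Seed points are first regularized by two Lloyd steps (centroidal
   Voronoi, computed exactly via mirror-image tessellation).
2. A spring joining two pinned rim nodes has frozen strain; if that
   strain exceeds the set point the spring deposits forever. Such
   rim-rim springs are removed as clipping artifacts.

Interior nodes are then placed at the harmonic (Tutte) embedding of the
graph with the rim fixed: with uniform spring constants and
`L0 = L/(1 + ε_home)`, the nodal force is proportional to the sum of
incident edge vectors, which the harmonic embedding zeroes. The
homeostatic, uniform-strain, all-`csa = 1` state is therefore an *exact,
stable* mechanical equilibrium (all springs in tension), and an
uninjured simulation is a true fixed point. Without this step the wide
strain spread of the raw geometry drives spontaneous fibrosis with no
injury at all.

Percolation validation deliberately uses the **raw** tessellation
(`lloyd_iterations=0, min_edge_frac=0`): edge contraction raises node
coordination and lowers the bond-percolation threshold to ≈ 0.62,
whereas the unmodified 2D Voronoi graph reproduces the reference
value ≈ 0.67.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `k0` | 1 | stiffness | unit spring constant; only ratios matter |
| `pre_stretch` | 1.1 | — | biaxial boundary stretch factor |
| `ε_home` | 0.1 | strain | homeostatic strain (= pre_stretch − 1) |
| `w1`, `w2` | 1.0, 1.3 | — | strain / stiffness response weights |
| `eps50`, `n_eps` | 0.06, 4 | strain, — | strain Hill half-max and exponent |
| `k50`, `n_k` | 5, 8 | stiffness, — | stiffness Hill half-max and exponent |
| `δ` (delta) | 0.15 | — | fractional csa change per agent visit |
| `csa_min`, `csa_max` | 0.1, 50 | — | digestion floor / deposition ceiling |
| agents per spring | 0.1 | — | agent density (≈ 1 agent per 10 springs) |
| injured fraction, csa | 0.2, 5 | — | standard injury protocol |
| injury iteration | 150 | iterations | injury time in the standard protocol |
| run length | 2000 | iterations | standard protocol horizon |

The Hill shapes and weights are the output of a calibration scan
(`scripts/calibrate_params.py`) against two requirements: an uninjured
network must be homeostatically stable, and the standard 20%/csa-5
injury must produce both healed and fibrotic outcomes across seeds.
Two shape choices do the work. `eps50 < ε_home` puts the strain response
near saturation at the set point, so digestion under low strain is
strong (deficit up to ≈ 0.9·w1) while deposition under excess strain is
weak and bounded (≤ 0.11·w1) — this lets the bulk of the network absorb
an injury transient without ratcheting upward. A steep stiffness Hill
(`n_k = 8`) keeps `a_K` negligible over the healthy csa range (no slow
uniform inflation of healthy tissue, which shallower exponents exhibit)
and concentrates the positive feedback just above the injury level, so
`K* ≈ 5.5` sits close to csa 5 and the bifurcation is reachable. The
`csa_max` ceiling is a numerical guard: locked springs otherwise grow
without bound (the saturated stiffness response exceeds the maximal
strain deficit by construction once `K > K*`).

`δ = 0.15` sets the remodeling timescale; healing of the standard injury
completes in roughly 400–600 post-injury iterations at the default agent
density. Test and example runs in this repository use a few hundred
iterations on networks of roughly 200–700 springs (seeds fixed
throughout); these sizes resolve the homeostasis, bifurcation and
regime properties while keeping runs to seconds each. The percolation
estimate uses 2000-cell networks and 200 replicates per grid point.

## Outcome classification

The stiffness trajectory of a run is labeled **healed** when the final
total stiffness is within `ratio_threshold` (default 1.25) times the
homogeneous baseline `K0 = N·k0` *and* the least-squares slope over the
final quarter of iterations does not exceed a small tolerance (default:
2% of `K0` net drift over the window); otherwise **fibrotic**. The rule
and both parameters are recorded inside every label. The 1.25 band
reflects the healed attractor of the calibrated model: injured springs
digest fully, but bulk springs that transiently deposited during the
injured phase settle at a strain-neutral level slightly above csa 1, so
healed runs plateau at ≈ 1.15–1.21 × K0 while fibrotic runs sit ≥ 1.3
with locked springs. A threshold at the plateau's center would split the
healed population in two.

An independent dynamical classification fits the reduced model
`dK/dt = −q(K − K0)`, closed form `K(t) = (K_i − K0)e^{−qt} + K0`, to the
post-injury trace by least squares (time origin at the injury, five
initial-rate starts, Levenberg–Marquardt) and reads the sign of `q̂`.
A trace that never leaves baseline (max deviation < 1e−9·K0) is flagged
unidentifiable rather than fitted.

## Geometry definitions

Spring adjacency means sharing at least one node. The clustering
coefficient of a focal spring counts distinct injured springs in
generations 0–2: the focal spring itself (iff injured), injured springs
adjacent to it, and injured springs adjacent to an *injured*
generation-1 spring — candidates reachable only through uninjured
intermediates are excluded, which disambiguates looped topologies.
Injury clusters are connected components of the injured-spring subgraph
(scipy sparse connected components; the test suite cross-checks against
networkx). Cluster diameters are maximum pairwise node distances;
intercluster distances are minimum pairwise node distances between
cluster node sets; both use Euclidean node positions at the injury
snapshot by default (the evaluation iteration is a parameter). In the
fibrotic-probability table, CC is recomputed at each requested iteration
on the *current* stiff set (`csa ≥ 5`), fibrosis-bound counts use the
final snapshot, and counts are pooled across runs; the denominator
defaults to all springs, with an option to restrict to injured springs.
Outcome-group comparisons pool per-cluster observations (each cluster's
nearest-neighbor distance and its diameter) across networks within a
group before the two-sample Kolmogorov–Smirnov test.

## Numerical choices

- Equilibrium: deterministic L-BFGS minimization of the elastic energy
  over free-node coordinates with analytic gradient; convergence when
  the largest nodal force magnitude falls below `tol × k0·max(csa)`
  (the achievable accuracy scales with the stiffest spring). Stalled
  line searches are retried with fresh memory, a Newton-CG polish
  (finite-differenced curvature), and finally a ~1e−9 deterministic
  jitter. A Metropolis simulated-annealing stage over single-node moves
  is available behind `method="anneal"` (followed by the same gradient
  polish); it exists for cross-checking, not speed. Defaults: `tol =
  1e−8` for standalone relaxation, `1e−7` inside simulations.
- Seeding: every stochastic component draws from a `numpy` Generator
  seeded explicitly; a single global seed expands into (network, injury,
  run) sub-seeds via `SeedSequence.spawn`, all < 2³¹. Identical seeds
  give bit-identical trajectories.
- Degenerate inputs: `n_seeds < 4` and empty domains are rejected;
  collinear seed layouts are retried with jitter a bounded number of
  times; empty injuries are legal no-ops; relaxation failure aborts a
  run with a partial trajectory and an error flag rather than raising.
- Bisection for the critical csa assumes the outcome is monotone in the
  hotspot's initial csa; a non-monotone sweep triggers a warning and
  returns the smallest transition.
- Percolation spanning = left and right bands (5% of the x-extent)
  joined through occupied springs; threshold by linear interpolation of
  the spanning probability across 0.5, with a delta-method standard
  error.

## Known limitations

- 2D only; linear springs; no viscoelasticity, airways, or multiple cell
  types. Injury is instantaneous.
- The healed state is a diffusely remodeled plateau slightly above
  baseline, not a bitwise return to `csa ≡ 1`: with activation depending
  only on (ε, K), any near-uniform csa field at homeostatic strain is
  neutral, so the plateau level is path-dependent.
- At the desk scales used here (a few hundred springs), injured clusters
  are small (≲ 5 springs) and fibrosis nucleates at individual
  strain-anchored springs. The local mechanism is as designed — the
  probability that a spring is fibrosis-bound rises steeply with its
  injury-time clustering coefficient, and fibrosis-bound springs carry
  roughly twice the post-injury strain of healing ones — but
  *network-level* contrasts between outcome groups in per-cluster
  distance and diameter distributions are not resolved at this size, and
  where measurable can even run opposite to the within-network trend.
  Resolving outcome-group geometry contrasts appears to require
  substantially larger networks, where injured clusters are long enough
  to anchor strain collectively.
- The percolating-stiffening dynamics of the simulator are
  mechanochemical and history-dependent; the classical bond-percolation
  estimate validates the substrate graph only and is not a model of the
  disease process.
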