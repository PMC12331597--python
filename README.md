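# fibronet

An agent-based spring-network model of pulmonary fibrosis, built to study
how the *spatial structure of an initial injury* decides whether injured
lung tissue heals or progresses to irreversible fibrosis.

Pulmonary fibrosis stiffens the extracellular matrix (ECM) through
excessive collagen deposition by activated fibroblasts. `fibronet`
represents the ECM as a two-dimensional Voronoi network of linear springs
— each spring `i` with rest length `L0_i`, cross-sectional area `csa_i`
(dimensionless, homeostatic value 1) and stiffness `K_i = k0·csa_i` —
held at a biaxial pre-stretch so every spring carries a homeostatic
strain `ε_home`. Fibroblast agents random-walk over the network; when an
agent traverses a spring it evaluates the spring's strain `ε` and
stiffness `K` and computes an activation

    a = w1·a_ε(ε) + w2·a_K(K) − c ,

where `a_ε` and `a_K` are Hill functions and `c` is calibrated so that
`a = 0` exactly at the homeostatic set point. Positive activation deposits
collagen (`csa ← csa·(1 + δ·a)`), negative digests it. The strain term is
a self-healing negative feedback; the stiffness term is a profibrotic
positive feedback, and the stiffness `K*` at which it outweighs the
largest possible strain deficit is the emergent *fibrotic threshold*.
One iteration = every agent steps across one spring, then the network is
re-solved for mechanical equilibrium (energy minimization over free
nodes).

The analysis layer quantifies the injury's geometry and the resulting
dynamics:

- a generation-limited **clustering coefficient** (CC) per spring: the
  number of injured springs within two shared-node generations, where
  generation-2 membership requires an injured generation-1 intermediate;
- connected **injury clusters**, their **maximum diameters** and pairwise
  **minimum Euclidean distances**;
- healed/fibrotic **outcome classification** of stiffness trajectories,
  and *fibrosis-bound* springs (`csa ≥ 5` at the final iteration);
- **hotspot sweeps**: recreate the identical injured network with one
  spring's initial csa varied, and bisect for the critical csa at which
  the outcome flips (the bifurcation point);
- the **1D reduced model** `dK/dt = −q(K − K0)` with solution
  `K(t) = (K_i − K0)·e^{−qt} + K0`, whose fitted `q` separates curable
  (`q > 0`) from fibrosis-bound (`q < 0`) trajectories;
- classical **bond percolation** on the Voronoi substrate (spanning
  threshold ≈ 0.67), kept deliberately separate from the simulator's
  mechanochemical stiffening.

## Worked example

```python
import fibronet as fn

net_seed, inj_seed, run_seed = fn.split_seed(5)
network = fn.generate_voronoi_network(160, rng_seed=net_seed)
injury = fn.random_injury(network, fraction=0.2, injured_csa=5.0,
                          rng_seed=inj_seed)
trajectory = fn.run_simulation(network, injury, n_iterations=500,
                               injury_iteration=50, rng_seed=run_seed)

label = fn.classify_outcome(trajectory)
report = fn.geometry_report(network, injury.spring_ids,
                            positions=trajectory.position_snapshots[50])
fit = fn.fit_reduced_model(trajectory)
```

This prints (via the obvious `print` calls):

```
network: 361 springs, baseline stiffness K0 = 361
injury: 72 springs at csa 5 in 44 clusters, largest cluster 5 springs
outcome: healed (final K / K0 = 1.190)
reduced model: q = +0.0043 -> healed
fibrosis-bound springs at iteration 500: 0
```

20% of springs were stiffened fivefold at iteration 50; over the
remaining 450 iterations the agents digested the injury and total
stiffness returned into the healed band around baseline, consistent with
the positive fitted relaxation rate `q`. Fibrotic runs instead end with
locked springs (`csa ≥ 5`) and a rising stiffness trajectory.

The engineered bifurcation scenario — two marginally stiff clusters
joined by a chain whose middle spring is the hotspot — is one call:

```python
net, injury, hotspot = fn.injury.bifurcation_fixture()
results = fn.hotspot_sweep(net, injury, hotspot, [1.0, 3.0, 5.0],
                           run_seed=7, n_iterations=600,
                           injury_iteration=50, n_agents=4)
critical = fn.find_critical_csa(results)
```

Low hotspot csa heals, high turns fibrotic; `find_critical_csa` brackets
the flip.

A CLI mirrors the library (`fibronet simulate | geometry | ensemble |
sweep | percolation | fit-reduced`, each with `--seed`, `--config`,
`--out`); every output directory contains a manifest that reproduces the
run bit-exactly.

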