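"""Calibration scan for the agent response defaults.

The reference parameter set shipped in ResponseParams must satisfy two
conditions: (a) an uninjured network is homeostatically stable, and
(b) the standard injury protocol (20% of springs at csa 5) produces
both healed and fibrotic outcomes across random-network replicates.
This script scans candidate (w2, eps50, k50, n_k, delta) combinations at
desk scale and reports, for each, the homeostatic drift and the outcome
mix, together with the emergent fibrotic-threshold stiffness. It is a
diagnostic tool: rerun it after changing any Hill-shape default.

Usage:
    python scripts/calibrate_params.py --seeds 8 --iterations 500 --out scan.csv
"""

from __future__ import annotations

import argparse
import itertools

import numpy as np
import pandas as pd

import fibronet as fn
from fibronet.agents import ResponseParams, calibrated, fibrotic_threshold_stiffness


def evaluate(params, n_seeds_net=160, n_runs=8, n_iterations=500):
    # homeostatic drift: no injury, fixed seed
    net0 = fn.generate_voronoi_network(n_seeds_net, rng_seed=0)
    homeo = fn.run_simulation(
        net0, None, n_iterations=min(300, n_iterations), params=params, rng_seed=0
    )
    drift = float(
        np.abs(homeo.total_stiffness - homeo.baseline_stiffness).max()
        / homeo.baseline_stiffness
    )

    outcomes = {"healed": 0, "fibrotic": 0}
    for seed in range(n_runs):
        net_seed, inj_seed, run_seed = fn.split_seed(seed)
        net = fn.generate_voronoi_network(n_seeds_net, rng_seed=net_seed)
        injury = fn.random_injury(net, 0.2, 5.0, rng_seed=inj_seed)
        traj = fn.run_simulation(
            net, injury, n_iterations=n_iterations, injury_iteration=50,
            params=params, rng_seed=run_seed,
        )
        if traj.error:
            continue
        outcomes[fn.classify_outcome(traj).label] += 1
    k_star = fibrotic_threshold_stiffness(params)
    return {
        "homeostatic_drift": drift,
        "n_healed": outcomes["healed"],
        "n_fibrotic": outcomes["fibrotic"],
        "lock_threshold_K": k_star if k_star is not None else np.nan,
    }


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seeds", type=int, default=8, help="runs per candidate")
    parser.add_argument("--iterations", type=int, default=500)
    parser.add_argument("--out", default="calibration_scan.csv")
    parser.add_argument(
        "--quick", action="store_true",
        help="evaluate only the shipped default set",
    )
    args = parser.parse_args()

    if args.quick:
        grid = [dict()]
    else:
        grid = [
            dict(w2=w2, eps50=e50, k50=k50, n_k=nk, delta=d)
            for w2, e50, k50, nk, d in itertools.product(
                (0.9, 1.1, 1.3, 1.5),
                (0.06, 0.08),
                (4.0, 5.0),
                (6.0, 8.0),
                (0.1, 0.15),
            )
        ]

    rows = []
    for kw in grid:
        params = calibrated(ResponseParams(**kw))
        row = dict(kw)
        row.update(
            evaluate(params, n_runs=args.seeds, n_iterations=args.iterations)
        )
        rows.append(row)
        print(row)
    pd.DataFrame(rows).to_csv(args.out, index=False)
    print(f"wrote {len(rows)} candidates to {args.out}")


if __name__ == "__main__":
    main()
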