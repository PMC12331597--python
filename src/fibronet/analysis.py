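"""Outcome classification, injury-geometry statistics, bifurcation sweeps,
percolation, and the 1D reduced stiffness model.

A run is classified healed when its total stiffness returns to (a band
around) the homogeneous baseline K0 = N * k0 and is not trending upward
at the end; otherwise it is fibrotic. "Fibrosis-bound" springs are
injured springs whose csa is still at or above the injury level
(csa >= 5) at the final iteration -- persistent stiffness after a long
healing period marks irreversible fibrosis.

The reduced model collapses the high-dimensional spring system onto one
ODE for total stiffness, dK/dt = -q K + K0, with closed-form solution
K(t) = (Ki - K0) exp(-q t) + K0. The structural parameter q > 0 for
curable configurations (stable fixed point at K0) and q < 0 for
fibrosis-bound ones (divergence), so the sign of a fitted q is a
one-parameter dynamical classification of a trajectory.

Bond percolation here is the classical random-occupation kind, used to
validate the network substrate (threshold ~0.67 for 2D Voronoi
networks); it is deliberately separate from the simulator's
mechanochemical stiffening, which connects stiff clusters through
high-strain bridges in a near-deterministic, rich-get-richer fashion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .agents import ResponseParams, Trajectory, run_simulation
from .exceptions import InvalidStateError, NoCrossingError
from .geometry import GeometryReport, clustering_coefficients
from .injury import InjuryPattern, modify_spring
from .network import SpatialNetwork

__all__ = [
    "OutcomeLabel",
    "ReducedModelFit",
    "PercolationEstimate",
    "fibrosis_bound_springs",
    "fibrotic_probability_by_cc",
    "classify_outcome",
    "hotspot_sweep",
    "find_critical_csa",
    "compare_outcome_geometry",
    "estimate_percolation_threshold",
    "reduced_model_solution",
    "fit_reduced_model",
]

HEALED = "healed"
FIBROTIC = "fibrotic"


@dataclass(frozen=True)
class OutcomeLabel:
    """Healed/fibrotic label together with the rule inputs that produced it."""

    label: str
    final_ratio: float
    ratio_threshold: float
    trend_slope: float
    trend_tolerance: float

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


def fibrosis_bound_springs(
    trajectory: Trajectory, csa_threshold: float = 5.0
) -> frozenset[int]:
    """Injured springs whose final-snapshot csa is >= csa_threshold (inclusive)."""
    if not trajectory.snapshots:
        raise InvalidStateError("trajectory has no final snapshot")
    final = trajectory.final_csa
    injured = trajectory.injured_ids
    return frozenset(j for j in injured if final[j] >= csa_threshold)


def fibrotic_probability_by_cc(
    trajectories: Sequence[Trajectory],
    iterations: Iterable[int],
    csa_threshold: float = 5.0,
    denominator: str = "all",
) -> pd.DataFrame:
    """Fibrotic probability as a function of CC and iteration, pooled.

    At each requested iteration, the CC of every spring is recomputed on
    the current stiff-spring set (csa >= csa_threshold at that
    iteration). For each (iteration, CC value), fibrosis-bound springs
    (those at or above threshold at the *final* iteration) and total
    springs are counted and pooled across trajectories; the fibrotic
    probability is the ratio of the pooled counts.

    ``denominator`` chooses which springs enter the totals: ``"all"``
    (every spring in the network, the default) or ``"injured"`` (only
    initially injured springs).
    """
    trajectories = list(trajectories)
    if not trajectories:
        raise ValueError("need at least one trajectory")
    if denominator not in {"all", "injured"}:
        raise ValueError("denominator must be 'all' or 'injured'")

    counts: dict[tuple[int, int], list[int]] = {}
    for traj in trajectories:
        bound = fibrosis_bound_springs(traj, csa_threshold)
        for t in iterations:
            t = int(t)
            if t not in traj.snapshots:
                raise ValueError(f"trajectory lacks a snapshot at iteration {t}")
            stiff = set(
                np.flatnonzero(traj.snapshots[t] >= csa_threshold).tolist()
            )
            pool = (
                range(traj.network.n_springs)
                if denominator == "all"
                else sorted(traj.injured_ids)
            )
            cc = clustering_coefficients(traj.network, stiff, pool)
            for j, value in cc.items():
                key = (t, value)
                entry = counts.setdefault(key, [0, 0])
                entry[1] += 1
                if j in bound:
                    entry[0] += 1

    rows = [
        {
            "iteration": t,
            "cc": ccv,
            "n_fibrosis_bound": nb,
            "n_total": nt,
            "probability": nb / nt,
        }
        for (t, ccv), (nb, nt) in sorted(counts.items())
    ]
    return pd.DataFrame(rows)


def classify_outcome(
    trajectory: Trajectory,
    baseline: float | None = None,
    ratio_threshold: float = 1.25,
    trend_window: float = 0.25,
    trend_tolerance: float | None = None,
) -> OutcomeLabel:
    """Label a trajectory healed or fibrotic.

    Healed iff (a) the final total stiffness is at most
    ``ratio_threshold * baseline`` and (b) the least-squares slope of
    K(t) over the final ``trend_window`` fraction of iterations does not
    exceed ``trend_tolerance`` (default: a net drift of 2% of baseline
    over the window). Both rule parameters are recorded in the label.
    """
    if trajectory.error is not None or trajectory.iterations.size < 8:
        raise InvalidStateError(
            "cannot classify a truncated or failed trajectory"
        )
    k0_total = trajectory.baseline_stiffness if baseline is None else float(baseline)
    k = trajectory.total_stiffness
    t = trajectory.iterations.astype(float)
    n_tail = max(4, int(round(trend_window * k.size)))
    slope = float(np.polyfit(t[-n_tail:], k[-n_tail:], 1)[0])
    if trend_tolerance is None:
        trend_tolerance = 0.02 * k0_total / n_tail
    final_ratio = float(k[-1] / k0_total)
    healed = final_ratio <= ratio_threshold and slope <= trend_tolerance
    return OutcomeLabel(
        label=HEALED if healed else FIBROTIC,
        final_ratio=final_ratio,
        ratio_threshold=float(ratio_threshold),
        trend_slope=slope,
        trend_tolerance=float(trend_tolerance),
    )


def hotspot_sweep(
    network: SpatialNetwork,
    injury: InjuryPattern,
    spring_id: int,
    csa_values: Iterable[float],
    run_seed: int | np.random.SeedSequence | None = 0,
    classify_kwargs: dict | None = None,
    **run_kwargs,
) -> list[tuple[float, OutcomeLabel, Trajectory]]:
    """Re-run the same injured network with one spring's initial csa swept.

    Every run recreates the identical network and injury and uses the
    same simulation seed; only the single spring's assigned csa differs.
    Results are ordered by csa value.
    """
    if spring_id not in injury.assignments:
        raise ValueError(f"spring {spring_id} is not part of the injury")
    classify_kwargs = classify_kwargs or {}
    results = []
    for value in sorted(float(v) for v in csa_values):
        pattern = modify_spring(injury, spring_id, value)
        traj = run_simulation(
            network, pattern, rng_seed=run_seed, **run_kwargs
        )
        label = classify_outcome(traj, **classify_kwargs)
        results.append((value, label, traj))
    return results


def find_critical_csa(
    outcome: Callable[[float], str | OutcomeLabel] | Sequence[tuple],
    low: float = 1.0,
    high: float = 5.0,
    tolerance: float = 0.1,
) -> float | None:
    """Bisect for the csa at which the outcome flips from healed to fibrotic.

    ``outcome`` is either a callable mapping a csa value to a label
    (evaluated with all seeds held fixed by the caller) or a sweep result
    list ``[(csa, label, ...), ...]``. Returns the bracket midpoint once
    the bracket is narrower than ``tolerance``, or ``None`` when both
    endpoints give the same outcome. Monotonicity (healed below,
    fibrotic above) is assumed; a non-monotone sweep triggers a warning
    and the smallest transition is returned.
    """

    def as_label(x) -> str:
        return x.label if isinstance(x, OutcomeLabel) else str(x)

    if not callable(outcome):
        sweep = sorted(outcome, key=lambda r: r[0])
        labels = [as_label(r[1]) for r in sweep]
        flips = [
            i for i in range(1, len(labels)) if labels[i] != labels[i - 1]
        ]
        if not flips:
            return None
        if len(flips) > 1:
            warnings.warn(
                "non-monotone outcomes in sweep; returning smallest transition"
            )
        i = flips[0]
        return 0.5 * (sweep[i - 1][0] + sweep[i][0])

    lo, hi = float(low), float(high)
    lab_lo, lab_hi = as_label(outcome(lo)), as_label(outcome(hi))
    if lab_lo == lab_hi:
        return None
    while hi - lo > tolerance:
        mid = 0.5 * (lo + hi)
        lab_mid = as_label(outcome(mid))
        if lab_mid == lab_lo:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def compare_outcome_geometry(
    healed_reports: Sequence[GeometryReport],
    fibrotic_reports: Sequence[GeometryReport],
) -> pd.DataFrame:
    """KS comparison of injury-geometry distributions between outcomes.

    Pools per-cluster observations across networks within each outcome
    group and runs a two-sample Kolmogorov-Smirnov test on (a) the
    per-cluster minimum intercluster distance and (b) the per-cluster
    maximum diameter. Returns one row per metric with the KS statistic,
    p-value, group medians, and the direction of the fibrotic shift.
    """
    from scipy.stats import ks_2samp

    if not healed_reports or not fibrotic_reports:
        raise ValueError("both outcome groups must be nonempty")

    def pool(reports: Sequence[GeometryReport], metric: str) -> np.ndarray:
        values: list[float] = []
        for rep in reports:
            if metric == "min_distance":
                values.extend(rep.min_distance_per_cluster().values())
            else:
                values.extend(rep.max_diameter.values())
        return np.asarray(values, dtype=float)

    rows = []
    for metric in ("min_distance", "max_diameter"):
        a = pool(healed_reports, metric)
        b = pool(fibrotic_reports, metric)
        if a.size < 2 or b.size < 2:
            raise ValueError(f"need >= 2 pooled observations per group for {metric}")
        ks = ks_2samp(a, b)
        med_h, med_f = float(np.median(a)), float(np.median(b))
        rows.append(
            {
                "metric": metric,
                "ks_statistic": float(ks.statistic),
                "p_value": float(ks.pvalue),
                "median_healed": med_h,
                "median_fibrotic": med_f,
                "fibrotic_direction": "smaller" if med_f < med_h else "larger",
                "n_healed": int(a.size),
                "n_fibrotic": int(b.size),
            }
        )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# Percolation


@dataclass(frozen=True)
class PercolationEstimate:
    """Spanning-probability curve and interpolated threshold."""

    threshold: float
    standard_error: float
    p_grid: np.ndarray
    spanning_probability: np.ndarray
    replicates: int

    def __float__(self) -> float:
        return self.threshold


def _spans(
    network: SpatialNetwork, occupied: np.ndarray, band: float = 0.05
) -> bool:
    """True iff occupied springs connect the left and right domain edges.

    Bands of width ``band`` * (x extent) at the two vertical edges define
    the terminal node sets.
    """
    x = network.positions[:, 0]
    xmin, xmax = float(x.min()), float(x.max())
    w = xmax - xmin
    left = x <= xmin + band * w
    right = x >= xmax - band * w
    edges = network.edges[occupied]
    if edges.size == 0:
        return bool(np.any(left & right))
    n = network.n_nodes
    adj = coo_matrix(
        (np.ones(len(edges)), (edges[:, 0], edges[:, 1])), shape=(n, n)
    )
    _, labels = connected_components(adj, directed=False)
    return bool(np.intersect1d(labels[left], labels[right]).size > 0)


def estimate_percolation_threshold(
    networks: SpatialNetwork | Sequence[SpatialNetwork] | Callable[[int], SpatialNetwork],
    p_grid: Sequence[float] | None = None,
    replicates: int = 200,
    rng_seed: int | np.random.SeedSequence | None = 0,
    band: float = 0.05,
    n_networks: int = 8,
) -> PercolationEstimate:
    """Monte-Carlo bond-percolation threshold on 2D Voronoi networks.

    For each occupation probability p on the grid, springs are occupied
    independently with probability p over ``replicates`` trials and the
    fraction of trials with a left-right spanning occupied cluster is
    recorded. The threshold is the p at which the spanning probability
    crosses 0.5, by linear interpolation between grid neighbors, with a
    delta-method standard error from the binomial error at the crossing.

    ``networks`` may be one network, a sequence of networks (cycled over
    replicates), or a callable ``seed -> network`` used to build
    ``n_networks`` instances.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if p_grid is None:
        p_grid = np.round(np.arange(0.60, 0.741, 0.02), 10)
    p_grid = np.asarray(sorted(float(p) for p in p_grid))
    rng = np.random.default_rng(rng_seed)

    if callable(networks):
        seeds = rng.integers(2**31, size=n_networks)
        nets = [networks(int(s)) for s in seeds]
    elif isinstance(networks, SpatialNetwork):
        nets = [networks]
    else:
        nets = list(networks)

    prob = np.empty(p_grid.size)
    for i, p in enumerate(p_grid):
        hits = 0
        for r in range(replicates):
            net = nets[r % len(nets)]
            occupied = rng.random(net.n_springs) < p
            hits += _spans(net, occupied, band=band)
        prob[i] = hits / replicates

    viol = np.flatnonzero(np.diff(prob) < -3.0 * np.sqrt(0.25 / replicates))
    if viol.size:
        warnings.warn("spanning probability noticeably non-monotone on grid")

    above = np.flatnonzero(prob >= 0.5)
    below = np.flatnonzero(prob < 0.5)
    if above.size == 0 or below.size == 0 or above[0] == 0:
        raise NoCrossingError(
            "p grid does not bracket the spanning-probability crossing"
        )
    i_hi = int(above[0])
    i_lo = i_hi - 1
    p_lo, p_hi = p_grid[i_lo], p_grid[i_hi]
    f_lo, f_hi = prob[i_lo], prob[i_hi]
    threshold = p_lo + (0.5 - f_lo) / (f_hi - f_lo) * (p_hi - p_lo)
    # binomial SE at the crossing propagated through the local slope
    slope = (f_hi - f_lo) / (p_hi - p_lo)
    se_f = np.sqrt(0.5 * 0.5 / replicates)
    se = float(se_f / max(slope, 1e-12))
    return PercolationEstimate(
        threshold=float(threshold),
        standard_error=se,
        p_grid=p_grid,
        spanning_probability=prob,
        replicates=replicates,
    )


# ----------------------------------------------------------------------
# Reduced 1D model


def reduced_model_solution(Ki: float, K0: float, q: float, t) -> np.ndarray | float:
    """Closed-form solution K(t) = (Ki - K0) exp(-q t) + K0 of dK/dt = -qK + K0.

    Note the baseline convention: the inhomogeneous term equals q*K0 in
    the normalized form used here, so K0 is the fixed point whenever
    q != 0 and K(0) = Ki.
    """
    t_arr = np.asarray(t, dtype=float)
    out = (Ki - K0) * np.exp(-q * t_arr) + K0
    return float(out) if np.ndim(t) == 0 else out


@dataclass(frozen=True)
class ReducedModelFit:
    """Least-squares fit of the reduced model to a stiffness trajectory."""

    q: float
    Ki: float
    K0: float
    residual_norm: float
    unidentifiable: bool
    n_points: int

    @property
    def classification(self) -> str | None:
        """healed for q > 0 (stable fixed point), fibrotic for q < 0."""
        if self.unidentifiable:
            return None
        return HEALED if self.q > 0 else FIBROTIC


def fit_reduced_model(
    trajectory: Trajectory | tuple[np.ndarray, np.ndarray],
    K0: float | None = None,
    start_iteration: int | None = None,
) -> ReducedModelFit:
    """Fit K(t) = (Ki - K0) exp(-q t) + K0 to post-injury total stiffness.

    ``trajectory`` is either a Trajectory (post-injury points are used)
    or a raw ``(t, K)`` pair. Time is measured from the first fitted
    point. A trajectory that never leaves the baseline (max deviation
    below 1e-9 * K0) is flagged unidentifiable and classification is
    deferred to :func:`classify_outcome`.
    """
    if isinstance(trajectory, Trajectory):
        if K0 is None:
            K0 = trajectory.baseline_stiffness
        t0 = (
            start_iteration
            if start_iteration is not None
            else (trajectory.injury_iteration or 0)
        )
        mask = trajectory.iterations > t0
        t = trajectory.iterations[mask].astype(float)
        k = trajectory.total_stiffness[mask]
        origin = float(t0)  # so Ki is the stiffness at the injury itself
    else:
        t, k = (np.asarray(v, dtype=float) for v in trajectory)
        if K0 is None:
            raise ValueError("K0 is required when fitting raw series")
        origin = float(t[0])
    if t.size < 10:
        raise ValueError("need at least 10 post-injury points to fit")
    K0 = float(K0)
    tt = t - origin
    y = k - K0

    if np.max(np.abs(y)) <= 1e-9 * K0:
        return ReducedModelFit(
            q=0.0, Ki=K0, K0=K0, residual_norm=0.0,
            unidentifiable=True, n_points=int(t.size),
        )

    def residual(theta: np.ndarray) -> np.ndarray:
        amp, q = theta
        return amp * np.exp(-np.clip(q * tt, -700, 700)) - y

    span = tt[-1] if tt[-1] > 0 else 1.0
    best = None
    for q0 in (-2.0 / span, -0.2 / span, 0.0, 0.2 / span, 2.0 / span):
        res = least_squares(
            residual, x0=[y[0] if abs(y[0]) > 1e-12 * K0 else y[np.argmax(np.abs(y))], q0],
            method="lm", max_nfev=2000,
        )
        if best is None or res.cost < best.cost:
            best = res
    amp, q = best.x
    return ReducedModelFit(
        q=float(q),
        Ki=float(K0 + amp),
        K0=K0,
        residual_norm=float(np.linalg.norm(best.fun)),
        unidentifiable=False,
        n_points=int(t.size),
    )
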