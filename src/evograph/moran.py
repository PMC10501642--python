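"""Microscopic Moran Birth-death updating with mutation.

One update step on a weighted digraph ``g`` with fitness vector ``f``:

1. *Birth*: node ``i`` is selected to reproduce with probability
   ``f_i / sum_j f_j``.
2. *Mutation*: with probability ``mu`` the offspring is a mutant whose
   fitness is drawn from the mutation kernel ``zeta(f', f_i)``; otherwise it
   inherits ``f_i``.
3. *Death*: the offspring replaces out-neighbour ``k`` of ``i`` with
   probability ``w_ik / sum_j w_ij`` (the parent itself if ``i`` is
   self-looped).

Time is counted in Moran steps (one update = one step).  A reproducer on a
sink node (zero outgoing weight; only the directed families without
self-loops have those) has nowhere to place its offspring, so the step
changes nothing.

Long mutation-selection trajectories and two-type (``mu = 0``) fixation
experiments run in compiled (numba) inner loops; :func:`moran_step` is the
plain reference implementation used to pin down the per-step probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .graphs import WeightedGraph, temperatures
from .kernels import MutationKernel

__all__ = [
    "PopulationState",
    "StepInfo",
    "TrajectorySummary",
    "FixationEstimate",
    "moran_step",
    "run_mutation_selection",
    "run_two_type_fixation",
    "initial_mutant_node",
]

_UNIFORM, _TRUNC_GAUSS = 0, 1


@dataclass
class PopulationState:
    """Fitness vector (one entry per node) plus a Moran step counter."""

    fitness: np.ndarray
    time: int = 0

    def __post_init__(self) -> None:
        f = np.asarray(self.fitness, dtype=float)
        if f.ndim != 1 or f.size < 2:
            raise ValueError("fitness must be a vector of length >= 2")
        if np.any(f <= 0):
            raise ValueError("fitness values must be positive")
        self.fitness = f

    @property
    def mean_fitness(self) -> float:
        return float(self.fitness.mean())


@dataclass(frozen=True)
class StepInfo:
    """What happened in one Moran step (for auditing and unit tests)."""

    reproducer: int
    target: int  # -1 when the reproducer was a sink node (null event)
    mutated: bool
    offspring_fitness: float


def moran_step(
    state: PopulationState,
    g: WeightedGraph,
    k: MutationKernel,
    mu: float,
    rng: np.random.Generator,
) -> tuple[PopulationState, StepInfo]:
    """One Moran Birth-death-with-mutation update (reference implementation)."""
    if not (0.0 <= mu <= 1.0):
        raise ValueError("mutation probability must lie in [0, 1]")
    f = state.fitness
    if f.size != g.n_nodes:
        raise ValueError("state and graph dimensions differ")
    probs = f / f.sum()
    i = int(rng.choice(f.size, p=probs))
    row = g.normalized()[i]
    row_sum = row.sum()
    if row_sum == 0.0:  # sink node: nowhere to place the offspring
        return PopulationState(f.copy(), state.time + 1), StepInfo(i, -1, False, np.nan)
    target = int(rng.choice(f.size, p=row))
    mutated = bool(rng.random() < mu)
    off = float(k.sample(f[i], rng)) if mutated else float(f[i])
    new_f = f.copy()
    new_f[target] = off
    return PopulationState(new_f, state.time + 1), StepInfo(i, target, mutated, off)


# ---------------------------------------------------------------------------
# compiled inner loops
# ---------------------------------------------------------------------------


@njit(cache=True)
def _draw_mutant(parent: float, kind: int, f_min: float, f_max: float, sigma: float) -> float:
    if kind == _UNIFORM:
        return f_min + np.random.random() * (f_max - f_min)
    # truncated Gaussian: resample until inside the closed domain, which
    # realises exactly the renormalized truncated density
    while True:
        v = parent + sigma * np.random.standard_normal()
        if f_min <= v <= f_max:
            return v


@njit(cache=True)
def _select_proportional(weights: np.ndarray, total: float) -> int:
    u = np.random.random() * total
    acc = 0.0
    for j in range(weights.size):
        acc += weights[j]
        if u < acc:
            return j
    return weights.size - 1


@njit(cache=True)
def _mutation_selection_loop(
    fitness: np.ndarray,
    w_norm: np.ndarray,
    row_tot: np.ndarray,
    mu: float,
    kind: int,
    f_min: float,
    f_max: float,
    sigma: float,
    n_steps: int,
    burn_in: int,
    thin: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    np.random.seed(seed)
    N = fitness.size
    n_rec = n_steps // thin
    mean_series = np.empty(n_rec)
    node_avg = np.zeros(N)
    n_avg = 0
    rec = 0
    for step in range(1, n_steps + 1):
        tot_f = 0.0
        for j in range(N):
            tot_f += fitness[j]
        i = _select_proportional(fitness, tot_f)
        if row_tot[i] > 0.0:
            tgt = _select_proportional(w_norm[i], row_tot[i])
            if mu >= 1.0 or (mu > 0.0 and np.random.random() < mu):
                fitness[tgt] = _draw_mutant(fitness[i], kind, f_min, f_max, sigma)
            else:
                fitness[tgt] = fitness[i]
        if step > burn_in:
            for j in range(N):
                node_avg[j] += fitness[j]
            n_avg += 1
        if step % thin == 0 and rec < n_rec:
            m = 0.0
            for j in range(N):
                m += fitness[j]
            mean_series[rec] = m / N
            rec += 1
    if n_avg > 0:
        node_avg /= n_avg
    return fitness, mean_series, node_avg


@njit(cache=True)
def _two_type_loop(
    mutant: np.ndarray,
    r: float,
    w_norm: np.ndarray,
    row_tot: np.ndarray,
    max_steps: int,
    seed: int,
) -> tuple[int, int]:
    """Run to absorption; returns (outcome, steps).

    outcome: 1 fixation, 0 extinction, -1 step limit hit.
    """
    np.random.seed(seed)
    N = mutant.size
    count = 0
    for j in range(N):
        count += mutant[j]
    fitness = np.empty(N)
    for j in range(N):
        fitness[j] = r if mutant[j] == 1 else 1.0
    steps = 0
    while 0 < count < N:
        if steps >= max_steps:
            return -1, steps
        steps += 1
        tot_f = count * r + (N - count) * 1.0
        i = _select_proportional(fitness, tot_f)
        if row_tot[i] == 0.0:
            continue
        tgt = _select_proportional(w_norm[i], row_tot[i])
        if mutant[tgt] != mutant[i]:
            count += mutant[i] - mutant[tgt]
            mutant[tgt] = mutant[i]
            fitness[tgt] = fitness[i]
    return (1 if count == N else 0), steps


# ---------------------------------------------------------------------------
# replicate drivers
# ---------------------------------------------------------------------------


@dataclass
class TrajectorySummary:
    """Ensemble statistics of mutation-selection trajectories.

    ``mean_series[j]`` is replicate ``j``'s population mean fitness sampled
    every ``thin`` steps; ``node_avg[j]`` its per-node time-averaged fitness
    after burn-in; ``final_fitness[j]`` the fitness vector at the final
    step.  ``ensemble_mean``/``ensemble_sd`` summarise the population mean
    fitness at the final recorded time across replicates.
    """

    times: np.ndarray
    mean_series: np.ndarray
    node_avg: np.ndarray
    final_fitness: np.ndarray
    n_replicates: int
    seed: int
    meta: dict = field(default_factory=dict)

    @property
    def ensemble_mean(self) -> float:
        return float(self.mean_series[:, -1].mean())

    @property
    def ensemble_sd(self) -> float:
        return float(self.mean_series[:, -1].std(ddof=1))

    @property
    def ensemble_se(self) -> float:
        return self.ensemble_sd / np.sqrt(self.n_replicates)

    def node_time_average(self) -> np.ndarray:
        """Per-node time-averaged fitness, pooled over replicates."""
        return self.node_avg.mean(axis=0)


def _replicate_seed(seed: int, j: int) -> int:
    """Decorrelated per-replicate stream seed.

    Consecutive integer seeds produce measurably correlated Mersenne-Twister
    streams (enough to bias ensemble statistics by >1 SE), so replicate
    ``j`` hashes ``(seed, j)`` through a SeedSequence instead.
    """
    return int(np.random.SeedSequence((seed, j)).generate_state(1)[0] % 2**31)


def run_mutation_selection(
    g: WeightedGraph,
    k: MutationKernel,
    mu: float,
    n_steps: int,
    n_replicates: int,
    seed: int,
    burn_in_fraction: float = 0.5,
    thin: int | None = None,
    initial_fitness: float | None = None,
) -> TrajectorySummary:
    """Ensemble of Moran mutation-selection trajectories.

    Replicate ``j`` runs on its own stream ``seed + j``; all replicates
    start homogeneous at ``initial_fitness`` (domain midpoint by default).
    """
    if n_steps <= 0:
        raise ValueError("n_steps must be positive")
    if not (0.0 <= burn_in_fraction < 1.0):
        raise ValueError("burn_in_fraction must lie in [0, 1)")
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates for ensemble statistics")
    if not (0.0 <= mu <= 1.0):
        raise ValueError("mutation probability must lie in [0, 1]")
    N = g.n_nodes
    w_norm = g.normalized()
    row_tot = w_norm.sum(axis=1)
    kind = _UNIFORM if k.kind == "uniform" else _TRUNC_GAUSS
    sigma = float(k.sigma or 0.0)
    f0 = float(initial_fitness if initial_fitness is not None else 0.5 * (k.f_min + k.f_max))
    if not (k.f_min <= f0 <= k.f_max):
        raise ValueError("initial fitness outside the kernel domain")
    thin = int(thin or max(1, n_steps // 200))
    burn_in = int(burn_in_fraction * n_steps)
    n_rec = n_steps // thin

    mean_series = np.empty((n_replicates, n_rec))
    node_avg = np.empty((n_replicates, N))
    final_fitness = np.empty((n_replicates, N))
    for j in range(n_replicates):
        fit, series, navg = _mutation_selection_loop(
            np.full(N, f0),
            w_norm,
            row_tot,
            float(mu),
            kind,
            k.f_min,
            k.f_max,
            sigma,
            int(n_steps),
            burn_in,
            thin,
            _replicate_seed(seed, j),
        )
        final_fitness[j] = fit
        mean_series[j] = series
        node_avg[j] = navg
    times = thin * np.arange(1, n_rec + 1)
    return TrajectorySummary(
        times=times,
        mean_series=mean_series,
        node_avg=node_avg,
        final_fitness=final_fitness,
        n_replicates=n_replicates,
        seed=seed,
        meta={
            "graph": g.family_tag,
            "kernel": (k.kind, k.f_min, k.f_max, k.sigma),
            "mu": mu,
            "n_steps": n_steps,
            "burn_in": burn_in,
            "thin": thin,
            "initial_fitness": f0,
        },
    )


def initial_mutant_node(g: WeightedGraph, init: str | int, rng: np.random.Generator) -> int:
    """Draw the node where a fresh mutant appears.

    ``"uniform"`` picks any node equally; ``"temperature"`` picks node ``j``
    with probability proportional to its temperature (how often it is
    replaced, hence where mutants arise during reproduction); an integer
    pins the node.
    """
    if isinstance(init, (int, np.integer)):
        if not (0 <= int(init) < g.n_nodes):
            raise ValueError("initial node out of range")
        return int(init)
    if init == "uniform":
        return int(rng.integers(g.n_nodes))
    if init == "temperature":
        T = temperatures(g)
        return int(rng.choice(g.n_nodes, p=T / T.sum()))
    raise ValueError(f"unknown initialisation scheme {init!r}")


@dataclass
class FixationEstimate:
    """Monte-Carlo fixation statistics for a single invading mutant.

    ``tau_fix``/``tau_ext`` are pooled conditional means over all fixing /
    non-fixing replicates.  ``tau_fix_T``/``tau_ext_T`` recombine the
    per-initial-node conditional means with the initialisation scheme's
    exact node weights -- the estimator whose expectation is the analytic
    temperature-initialised time (which weighs starting nodes by
    temperature alone, not by their conditional outcome probability).
    """

    phi: float
    phi_se: float
    tau_fix: float
    tau_fix_se: float
    tau_ext: float
    tau_ext_se: float
    n_fixed: int
    n_extinct: int
    n_truncated: int
    n_replicates: int
    seed: int
    tau_fix_T: float = np.nan
    tau_fix_T_se: float = np.nan
    tau_ext_T: float = np.nan
    tau_ext_T_se: float = np.nan
    meta: dict = field(default_factory=dict)

    @property
    def no_fixation_observed(self) -> bool:
        return self.n_fixed == 0


def _cond_mean_se(times: np.ndarray) -> tuple[float, float]:
    if times.size == 0:
        return np.nan, np.nan
    if times.size == 1:
        return float(times[0]), np.nan
    return float(times.mean()), float(times.std(ddof=1) / np.sqrt(times.size))


def run_two_type_fixation(
    g: WeightedGraph,
    r: float,
    init: str | int,
    n_replicates: int,
    seed: int,
    max_steps: int = 10**9,
) -> FixationEstimate:
    """Estimate fixation probability and conditional absorption times.

    Each replicate seeds one mutant of relative fitness ``r`` (wild-type 1)
    at a node drawn per ``init`` and runs ``mu = 0`` dynamics to absorption.
    Conditional mean times average fixing and non-fixing replicates
    separately.  Replicates hitting ``max_steps`` are reported truncated and
    excluded from the conditional means.
    """
    if r <= 0:
        raise ValueError("relative fitness must be positive")
    w_norm = g.normalized()
    row_tot = w_norm.sum(axis=1)
    rng = np.random.default_rng(seed)
    outcomes = np.empty(n_replicates, dtype=np.int64)
    steps = np.empty(n_replicates, dtype=np.int64)
    nodes = np.empty(n_replicates, dtype=np.int64)
    for j in range(n_replicates):
        node = initial_mutant_node(g, init, rng)
        nodes[j] = node
        mutant = np.zeros(g.n_nodes, dtype=np.int64)
        mutant[node] = 1
        outcomes[j], steps[j] = _two_type_loop(
            mutant, float(r), w_norm, row_tot, int(max_steps), _replicate_seed(seed, j)
        )
    fixed = outcomes == 1
    extinct = outcomes == 0
    n_fixed, n_ext = int(fixed.sum()), int(extinct.sum())
    n_done = n_fixed + n_ext
    phi = n_fixed / n_done if n_done else np.nan
    phi_se = np.sqrt(phi * (1 - phi) / n_done) if n_done else np.nan
    tau_fix, tau_fix_se = _cond_mean_se(steps[fixed].astype(float))
    tau_ext, tau_ext_se = _cond_mean_se(steps[extinct].astype(float))

    if init == "temperature":
        T = temperatures(g)
        node_w = T / T.sum()
    elif init == "uniform":
        node_w = np.full(g.n_nodes, 1.0 / g.n_nodes)
    else:
        node_w = np.zeros(g.n_nodes)
        node_w[int(init)] = 1.0

    def scheme_weighted(cond: np.ndarray) -> tuple[float, float]:
        # nodes with < 2 conditioned events are dropped and the weights
        # renormalized (bias bounded by the dropped weight share)
        total, var, w_used = 0.0, 0.0, 0.0
        for node in np.flatnonzero(node_w > 0):
            m, se = _cond_mean_se(steps[cond & (nodes == node)].astype(float))
            if not (np.isfinite(m) and np.isfinite(se)):
                continue
            total += node_w[node] * m
            var += (node_w[node] * se) ** 2
            w_used += node_w[node]
        if w_used == 0.0:
            return np.nan, np.nan
        return total / w_used, float(np.sqrt(var)) / w_used

    tau_fix_T, tau_fix_T_se = scheme_weighted(fixed)
    tau_ext_T, tau_ext_T_se = scheme_weighted(extinct)
    return FixationEstimate(
        phi=float(phi),
        phi_se=float(phi_se),
        tau_fix=tau_fix,
        tau_fix_se=tau_fix_se,
        tau_ext=tau_ext,
        tau_ext_se=tau_ext_se,
        n_fixed=n_fixed,
        n_extinct=n_ext,
        n_truncated=int((outcomes == -1).sum()),
        n_replicates=n_replicates,
        seed=seed,
        tau_fix_T=tau_fix_T,
        tau_fix_T_se=tau_fix_T_se,
        tau_ext_T=tau_ext_T,
        tau_ext_T_se=tau_ext_T_se,
        meta={"graph": g.family_tag, "r": r, "init": init},
    )
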