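"""Mutation-selection balance: analytic and quadrature steady states.

Low mutation rate
-----------------
Below the mutation-rate threshold the population is effectively monomorphic
and its fitness performs a random walk on ``[f_min, f_max]``: a mutant of
fitness ``f'`` arises from a resident of fitness ``f`` at rate
``mu * zeta(f', f)`` (on a high-temperature node, hence the
temperature-initialised fixation probability) and carries the whole
population with probability ``phi_T(f', f)``.  Assuming detailed balance of
this jump chain the stationary density is

    P*(f)  propto  1 / Integral df' [phi_T(f', f)/phi_T(f, f')]
                                  * [zeta(f', f)/zeta(f, f')].

High mutation rate (mu -> 1)
----------------------------
On the self-looped complete graph every node is equally likely to receive
each mutant offspring, node fitnesses decorrelate, and with the uniform
kernel the per-node marginal is flat: population mean ``(f_min + f_max)/2``
independent of ``N``, population standard deviation
``(f_max - f_min)/sqrt(12 N)``.  Reversibility of the coarse-grained chain
is certified by Kolmogorov's cycle criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .chains import complete_fixation_prob, star_phi_T
from .kernels import MutationKernel

__all__ = [
    "SteadyStateResult",
    "low_mu_stationary",
    "complete_low_mu_mean",
    "high_mu_selflooped_complete",
    "temperature_fixation_function",
    "low_mu_mean_for_family",
    "independent_jump_density",
    "single_update_density",
    "kolmogorov_check",
]


@dataclass
class SteadyStateResult:
    """Stationary fitness density on a uniform grid plus summary moments."""

    grid: np.ndarray
    density: np.ndarray
    mean: float
    sd: float
    regime: str  # "low_mu" | "high_mu"
    meta: dict = field(default_factory=dict)

    def normalization(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


def _moments(grid: np.ndarray, density: np.ndarray) -> tuple[float, float]:
    mean = float(np.trapezoid(grid * density, grid))
    var = float(np.trapezoid((grid - mean) ** 2 * density, grid))
    return mean, np.sqrt(max(var, 0.0))


def low_mu_stationary(
    phi_fn: Callable[[np.ndarray, np.ndarray], np.ndarray],
    k: MutationKernel,
    grid_size: int = 2001,
) -> SteadyStateResult:
    """Detailed-balance stationary density of the low-mu fitness walk.

    ``phi_fn(f_prime, f)`` must give the temperature-initialised fixation
    probability of an ``f_prime``-mutant in an ``f``-resident population,
    vectorized over numpy arrays.  The ratio integral runs over the kernel
    domain by trapezoid quadrature; ratios are formed in log space so that
    strongly beneficial/deleterious pairs cannot overflow.
    """
    if grid_size < 101:
        raise ValueError("grid_size must be at least 101")
    f = np.linspace(k.f_min, k.f_max, grid_size)
    fp, fr = np.meshgrid(f, f, indexing="ij")  # fp: mutant f', fr: resident f
    with np.errstate(divide="ignore", over="ignore"):
        log_phi = np.log(np.asarray(phi_fn(fp, fr), dtype=float))
        log_ratio = log_phi - log_phi.T
        if k.kind != "uniform":
            zeta = np.asarray(k.density(fp, fr), dtype=float)
            log_ratio += np.log(zeta) - np.log(zeta.T)
        ratio = np.exp(log_ratio)
    # integrate over f' (axis 0) for every resident fitness f
    denom = np.trapezoid(ratio, f, axis=0)
    density = 1.0 / denom
    density /= np.trapezoid(density, f)
    mean, sd = _moments(f, density)
    return SteadyStateResult(
        grid=f,
        density=density,
        mean=mean,
        sd=sd,
        regime="low_mu",
        meta={"kernel": (k.kind, k.f_min, k.f_max, k.sigma), "grid_size": grid_size},
    )


def complete_low_mu_mean(N: int, f_min: float, f_max: float) -> float:
    """Closed-form low-mu steady-state mean fitness of the complete graph.

    ``<f> = N/(N+1) * (f_max^{N+1} - f_min^{N+1}) / (f_max^N - f_min^N)``
    (uniform kernel), evaluated through the ratio ``f_min/f_max < 1`` so it
    is stable for large ``N``.
    """
    if N < 1:
        raise ValueError("N must be positive")
    if not (0.0 < f_min < f_max):
        raise ValueError("need 0 < f_min < f_max")
    rho = f_min / f_max
    return N / (N + 1.0) * f_max * (-np.expm1((N + 1) * np.log(rho))) / (-np.expm1(N * np.log(rho)))


def high_mu_selflooped_complete(
    f_min: float,
    f_max: float,
    N: int,
    grid_size: int = 2001,
    kernel: MutationKernel | None = None,
) -> SteadyStateResult:
    """Exact mu -> 1 steady state on the self-looped complete graph.

    Valid for the uniform kernel only (pass ``kernel`` to assert that); each
    node's marginal is flat on the domain, so the population mean is the
    domain midpoint for every ``N`` while the population-mean fluctuation
    shrinks as ``1/sqrt(N)``.
    """
    if kernel is not None and kernel.kind != "uniform":
        raise ValueError(
            "no closed form for a non-uniform kernel; use the Moran simulator instead"
        )
    if N < 1:
        raise ValueError("N must be positive")
    if not (0.0 < f_min < f_max):
        raise ValueError("need 0 < f_min < f_max")
    grid = np.linspace(f_min, f_max, grid_size)
    density = np.full(grid_size, 1.0 / (f_max - f_min))
    return SteadyStateResult(
        grid=grid,
        density=density,
        mean=0.5 * (f_min + f_max),
        sd=(f_max - f_min) / np.sqrt(12.0 * N),
        regime="high_mu",
        meta={"N": N, "marginal": "uniform per node"},
    )


def temperature_fixation_function(
    family: str, N: int, params: dict | None = None
) -> Callable[[np.ndarray, np.ndarray], np.ndarray]:
    """``phi_T(f', f)`` for the graph families with known reductions.

    The two-type reduction sees fitness only through the ratio
    ``r = f'/f``.  ``complete`` and ``cycle`` share the isothermal formula;
    star families use the weighted-star closed form; on the self-looped
    directed line only a root-seeded mutant can fix and then always does, so
    ``phi_T = T_root/N`` independent of fitness.
    """
    params = dict(params or {})
    n = N - 1
    if family in ("complete", "cycle"):
        return lambda fp, f: complete_fixation_prob(fp, f, N)
    if family == "star":
        return lambda fp, f: star_phi_T(n, 1.0, 1.0, np.asarray(fp) / np.asarray(f))
    if family == "selflooped_weighted_star":
        lam = float(params.get("lam", 1.0 / n))
        delta = float(params.get("delta", 1.0 / n**2))
        return lambda fp, f: star_phi_T(n, lam, delta, np.asarray(fp) / np.asarray(f))
    if family == "selflooped_directed_line":
        # root temperature is 1/2 (its own half-weight self-loop)
        const = 0.5 / N
        return lambda fp, f: np.full(np.broadcast(np.asarray(fp), np.asarray(f)).shape, const)
    raise ValueError(f"no analytic temperature-initialised phi for family {family!r}")


def low_mu_mean_for_family(
    family: str,
    N: int,
    k: MutationKernel,
    params: dict | None = None,
    grid_size: int = 2001,
) -> float:
    """Quadrature low-mu steady-state mean for a named graph family."""
    res = low_mu_stationary(temperature_fixation_function(family, N, params), k, grid_size)
    return res.mean


def independent_jump_density(k: MutationKernel) -> Callable[[np.ndarray, np.ndarray], float]:
    """Coarse-grained (full-sweep) transition density of the self-looped
    complete graph: ``T(f <- f') = prod_i zeta(f_i, f'_i)`` -- every node's
    new fitness is an independent kernel draw from its previous occupant.

    Over any closed cycle the kernel masses telescope, so this density
    satisfies Kolmogorov's criterion *identically*, for every kernel: the
    sweep-level chain is always reversible.  Kernel-induced irreversibility
    only shows at the single-update level (:func:`single_update_density`).
    """

    def T(f_to: np.ndarray, f_from: np.ndarray) -> float:
        f_to = np.asarray(f_to, dtype=float)
        f_from = np.asarray(f_from, dtype=float)
        return float(np.prod(k.density(f_to, f_from)))

    return T


def single_update_density(k: MutationKernel) -> Callable[[np.ndarray, np.ndarray], float]:
    """One-Moran-step transition density on the self-looped complete graph
    at ``mu = 1``.

    States reachable in one step differ in exactly one coordinate ``j``;
    the reproducing parent is fitness-selected, the target uniform:
    ``T(f' <- f) = (1/N) sum_i (f_i / sum f) zeta(f'_j, f_i)``.  For the
    uniform kernel this is fitness-independent (reversible); a parent-
    centred kernel makes cycles irreversible.
    """

    def T(f_to: np.ndarray, f_from: np.ndarray) -> float:
        f_to = np.asarray(f_to, dtype=float)
        f_from = np.asarray(f_from, dtype=float)
        changed = np.flatnonzero(f_to != f_from)
        if changed.size != 1:
            return 0.0
        j = changed[0]
        N = f_from.size
        sel = f_from / f_from.sum()
        return float(np.sum(sel * k.density(np.full(N, f_to[j]), f_from)) / N)

    return T


def kolmogorov_check(
    transition_density_fn: Callable[[np.ndarray, np.ndarray], float],
    state_cycle: Sequence[np.ndarray],
) -> float:
    """Kolmogorov cycle criterion: forward/backward transition product ratio.

    A ratio of 1 on every cycle certifies reversibility (and hence detailed
    balance).  The cycle is closed automatically if the last state differs
    from the first.  A zero density along one direction is returned as 0.0
    or ``inf`` -- evidence of irreversibility, not an error.
    """
    states = [np.asarray(s, dtype=float) for s in state_cycle]
    if len(states) < 3:
        raise ValueError("a cycle needs at least 3 states")
    if not np.array_equal(states[0], states[-1]):
        states = states + [states[0]]
    log_fwd = 0.0
    log_bwd = 0.0
    fwd_zero = bwd_zero = False
    for a, b in zip(states[:-1], states[1:]):
        f = transition_density_fn(b, a)  # a -> b
        g = transition_density_fn(a, b)  # b -> a
        if f <= 0.0:
            fwd_zero = True
        else:
            log_fwd += np.log(f)
        if g <= 0.0:
            bwd_zero = True
        else:
            log_bwd += np.log(g)
    if fwd_zero and bwd_zero:
        return np.nan
    if fwd_zero:
        return 0.0
    if bwd_zero:
        return np.inf
    return float(np.exp(log_fwd - log_bwd))
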