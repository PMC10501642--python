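"""Exact two-type absorption analytics on reduced Markov chains.

For a single mutant type (relative fitness ``r``) invading a wild-type
population (fitness 1) under Moran Birth-death updating, the dynamics on
highly symmetric graphs reduces to a one-dimensional Markov chain:

* star family (center + ``n`` leaves, weights ``lam`` leaf->center and
  ``delta/n`` center->leaf, self-loops on the diagonal): states ``(•, i)``
  and ``(∘, i)`` -- a mutant (filled) or wild-type (open) center with ``i``
  mutant leaves;
* complete graph and cycle: a birth-death chain on the mutant count ``i``;
* self-looped directed line: a pure-birth chain for fixation (only a mutant
  seeded at the root can fix) plus a pure-death approximation for
  extinction.

Fixation probabilities follow the standard ratio-of-products formulas.
Conditional mean absorption times are obtained exactly by solving the
linear system satisfied by ``psi = phi * tau`` on the conditional jump
chain: ``psi_s = sum_s' pi(s -> s') psi_s' + phi_s * t_s`` with ``t_s`` the
mean sojourn time of state ``s`` and ``psi = 0`` at both absorbing states.
The same system with the extinction probabilities on the right-hand side
yields conditional extinction times.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import scipy.sparse as sp
from scipy.linalg import solve_banded
from scipy.sparse.linalg import spsolve
from scipy.special import logsumexp

__all__ = [
    "StarChain",
    "BDChain",
    "AbsorptionSummary",
    "star_chain",
    "star_fixation",
    "star_extinction",
    "star_temperature_summary",
    "star_phi_T",
    "star_neutral_closed_forms",
    "star_neutral_tau_T_closed",
    "harmonic_number",
    "family_chain",
    "bd_chain_absorption",
    "complete_fixation_prob",
    "directed_line_times",
]

_NEUTRAL_TOL = 1e-10


def harmonic_number(n: int) -> float:
    """``H_n = sum_{k=1}^n 1/k`` by direct summation."""
    if n < 0:
        raise ValueError("n must be non-negative")
    return float(np.sum(1.0 / np.arange(1, n + 1)))


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------


@dataclass
class AbsorptionSummary:
    """Fixation/extinction probabilities and conditional mean times.

    Per-initial-state arrays are indexed by the chain's own state labels
    (mutant count for birth-death chains; see the producing function).
    ``phi_T``/``tau_T``/``tau_ext_T`` are the temperature-initialised
    aggregates: quantities for a single new mutant placed on a node with
    probability proportional to its temperature.  ``*_se`` fields are only
    set by stochastic estimators.
    """

    fixation_prob: np.ndarray
    cond_fixation_time: np.ndarray
    extinction_prob: np.ndarray
    cond_extinction_time: np.ndarray
    phi_T: float | None = None
    tau_T: float | None = None
    tau_ext_T: float | None = None
    phi_T_se: float | None = None
    tau_T_se: float | None = None
    tau_ext_T_se: float | None = None
    n_runs: int | None = None
    meta: dict = field(default_factory=dict)


@dataclass
class StarAbsorption:
    """Arrays indexed by the leaf-mutant count ``i = 0..n``.

    ``*_center`` refers to initial states with a mutant center ``(•, i)``;
    ``*_leaf`` to a wild-type center ``(∘, i)``.  Entries that condition on
    an impossible event (e.g. fixation time from ``(∘, 0)``) are NaN.
    """

    phi_center: np.ndarray
    phi_leaf: np.ndarray
    tau_center: np.ndarray
    tau_leaf: np.ndarray

    @property
    def tau_0_center(self) -> float:
        return float(self.tau_center[0])

    @property
    def tau_1_leaf(self) -> float:
        return float(self.tau_leaf[1])


# ---------------------------------------------------------------------------
# star family
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StarChain:
    """Reduced two-type chain for the self-looped weighted star graph.

    ``n`` leaves, center node 0; leaf->center weight ``lam``, center->leaf
    weight ``delta/n``, self-loops ``1 - lam`` and ``1 - delta``.  The plain
    star graph is ``lam = delta = 1``.  ``r`` is the mutant's fitness
    relative to the wild-type.
    """

    n: int
    lam: float
    delta: float
    r: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need at least 2 leaves")
        if not (0.0 < self.lam <= 1.0 and 0.0 < self.delta <= 1.0):
            raise ValueError("parameters must satisfy 0 < lam <= 1, 0 < delta <= 1")
        if self.r <= 0:
            raise ValueError("relative fitness must be positive")

    # -- microscopic transition probabilities (per Moran step) -----------
    def T_up_center(self) -> np.ndarray:
        """``T••_{i,i+1}`` for ``i = 0..n-1``: mutant center reproduces onto
        a wild-type leaf."""
        n, r, d = self.n, self.r, self.delta
        i = np.arange(n)
        return r / (r + i * r + n - i) * (d / n) * (n - i)

    def T_down_center(self) -> np.ndarray:
        """``T•∘_{i,i}`` for ``i = 0..n-1``: a wild-type leaf reproduces onto
        the mutant center."""
        n, r, lam = self.n, self.r, self.lam
        i = np.arange(n)
        return (n - i) / (r + i * r + n - i) * lam

    def T_up_leaf(self) -> np.ndarray:
        """``T∘•_{i,i}`` for ``i = 1..n`` (index ``i-1``): a mutant leaf
        reproduces onto the wild-type center."""
        n, r, lam = self.n, self.r, self.lam
        i = np.arange(1, n + 1)
        return i * r / (1 + i * r + n - i) * lam

    def T_down_leaf(self) -> np.ndarray:
        """``T∘∘_{i,i-1}`` for ``i = 1..n`` (index ``i-1``): the wild-type
        center reproduces onto a mutant leaf."""
        n, r, d = self.n, self.r, self.delta
        i = np.arange(1, n + 1)
        return 1 / (1 + i * r + n - i) * (d / n) * i

    # -- conditional (jump-chain) probabilities; independent of i --------
    @property
    def pi_up_center(self) -> float:
        n, r = self.n, self.r
        return r * self.delta / (n * self.lam + r * self.delta)

    @property
    def pi_down_center(self) -> float:
        return 1.0 - self.pi_up_center

    @property
    def pi_up_leaf(self) -> float:
        n, r = self.n, self.r
        return n * self.lam * r / (n * self.lam * r + self.delta)

    @property
    def pi_down_leaf(self) -> float:
        return 1.0 - self.pi_up_leaf

    def sojourn_center(self) -> np.ndarray:
        """Mean Moran steps spent in ``(•, i)``, ``i = 0..n-1``."""
        return 1.0 / (self.T_up_center() + self.T_down_center())

    def sojourn_leaf(self) -> np.ndarray:
        """Mean Moran steps spent in ``(∘, i)``, ``i = 1..n`` (index i-1)."""
        return 1.0 / (self.T_up_leaf() + self.T_down_leaf())

    # -- temperature weights ---------------------------------------------
    @property
    def center_temperature(self) -> float:
        return 1.0 - self.delta + self.n * self.lam

    @property
    def leaf_temperature(self) -> float:
        return self.delta / self.n + 1.0 - self.lam

    def temperature_weights(self) -> tuple[float, float]:
        """Probabilities that a fresh mutant lands on the center / any leaf."""
        N = self.n + 1
        return self.center_temperature / N, self.n * self.leaf_temperature / N


def star_chain(n: int, lam: float, delta: float, r: float) -> StarChain:
    """Build the reduced two-type chain for a self-looped weighted star."""
    return StarChain(n=n, lam=lam, delta=delta, r=r)


def _log_A(c: StarChain, l: int, m: int) -> float:
    """``log A(l, m)`` with ``A = 1 + pi_down_center * sum_{t=1}^{m-l} q^t``
    and ``q = pi_down_leaf / pi_up_center`` (log-space against overflow)."""
    if m <= l:
        return 0.0
    log_q = np.log(c.pi_down_leaf) - np.log(c.pi_up_center)
    t = np.arange(1, m - l + 1)
    log_geom = logsumexp(t * log_q)
    return float(logsumexp([0.0, np.log(c.pi_down_center) + log_geom]))


def _star_phi(c: StarChain) -> tuple[np.ndarray, np.ndarray]:
    """Fixation probabilities ``phi_i_center`` and ``phi_i_leaf``, i = 0..n."""
    n = c.n
    log_A1n = _log_A(c, 1, n)
    phi_center = np.empty(n + 1)
    for i in range(1, n + 1):
        phi_center[i] = np.exp(_log_A(c, 1, i) - log_A1n)
    # boundary state (•, 0): one conditional jump up to (•, 1) or down to
    # extinction, so phi_0_center = pi_up_center * phi_1_center
    phi_center[0] = c.pi_up_center * phi_center[1]
    phi_leaf = np.zeros(n + 1)
    for i in range(1, n + 1):
        phi_leaf[i] = c.pi_down_leaf * phi_leaf[i - 1] + c.pi_up_leaf * phi_center[i]
    return phi_center, phi_leaf


def _star_conditional_times(
    c: StarChain, phi_center: np.ndarray, phi_leaf: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Solve the conditional-time linear system for ``psi = phi * tau``.

    ``phi`` may be either the fixation or the extinction probabilities; the
    coefficient matrix (the conditional jump chain) is the same.  Returns
    ``(tau_center, tau_leaf)`` with NaN where the conditioning probability
    vanishes.  Unknowns: ``y_i = psi(•, i)`` for ``i = 0..n-1`` and
    ``z_i = psi(∘, i)`` for ``i = 1..n``; the absorbing states ``(•, n)``
    and ``(∘, 0)`` have ``psi = 0``.
    """
    n = c.n
    t_c = c.sojourn_center()  # i = 0..n-1
    t_l = c.sojourn_leaf()  # i = 1..n at index i-1

    def y_idx(i: int) -> int:
        return 2 * i

    def z_idx(i: int) -> int:
        return 2 * i - 1

    size = 2 * n
    rows, cols, vals = [], [], []
    b = np.zeros(size)
    for i in range(n):  # equations for y_i
        req = y_idx(i)
        rows.append(req), cols.append(y_idx(i)), vals.append(1.0)
        if i + 1 <= n - 1:
            rows.append(req), cols.append(y_idx(i + 1)), vals.append(-c.pi_up_center)
        if i >= 1:
            rows.append(req), cols.append(z_idx(i)), vals.append(-c.pi_down_center)
        b[req] = phi_center[i] * t_c[i]
    for i in range(1, n + 1):  # equations for z_i
        req = z_idx(i)
        rows.append(req), cols.append(z_idx(i)), vals.append(1.0)
        if i <= n - 1:
            rows.append(req), cols.append(y_idx(i)), vals.append(-c.pi_up_leaf)
        if i >= 2:
            rows.append(req), cols.append(z_idx(i - 1)), vals.append(-c.pi_down_leaf)
        b[req] = phi_leaf[i] * t_l[i - 1]
    M = sp.csr_matrix((vals, (rows, cols)), shape=(size, size))
    x = spsolve(M, b)

    with np.errstate(divide="ignore", invalid="ignore"):
        tau_center = np.full(n + 1, np.nan)
        tau_leaf = np.full(n + 1, np.nan)
        for i in range(n):
            tau_center[i] = x[y_idx(i)] / phi_center[i] if phi_center[i] > 0 else np.nan
        tau_center[n] = 0.0 if phi_center[n] > 0 else np.nan
        for i in range(1, n + 1):
            tau_leaf[i] = x[z_idx(i)] / phi_leaf[i] if phi_leaf[i] > 0 else np.nan
        tau_leaf[0] = 0.0 if phi_leaf[0] > 0 else np.nan
    return tau_center, tau_leaf


def star_fixation(c: StarChain) -> StarAbsorption:
    """Fixation probabilities and conditional mean fixation times.

    ``phi`` follows the closed-form products of conditional transition
    probabilities; times solve the conditional-jump-chain linear system.
    """
    phi_center, phi_leaf = _star_phi(c)
    tau_center, tau_leaf = _star_conditional_times(c, phi_center, phi_leaf)
    return StarAbsorption(phi_center, phi_leaf, tau_center, tau_leaf)


def star_extinction(c: StarChain) -> StarAbsorption:
    """Extinction probabilities (``1 - phi``) and conditional extinction times.

    The index-reversal symmetry of the reduced chain means the extinction
    problem satisfies the same conditional-time system with the extinction
    probabilities on the right-hand side; no separate recursion is needed.
    """
    phi_center, phi_leaf = _star_phi(c)
    ext_center = 1.0 - phi_center
    ext_leaf = 1.0 - phi_leaf
    # absorbing roles swap: (∘, 0) is the target, (•, n) the miss
    tau_center, tau_leaf = _star_conditional_times(c, ext_center, ext_leaf)
    return StarAbsorption(ext_center, ext_leaf, tau_center, tau_leaf)


def star_temperature_summary(c: StarChain) -> AbsorptionSummary:
    """Temperature-initialised aggregates for a single fresh mutant.

    A new mutant lands on the center (state ``(•, 0)``) with probability
    ``T_center/(n+1)`` and on a leaf (state ``(∘, 1)``) with probability
    ``n * T_leaf/(n+1)``; the two weights sum to one for every ``lam,
    delta`` (temperature conservation).
    """
    fix = star_fixation(c)
    ext = star_extinction(c)
    w_center, w_leaf = c.temperature_weights()
    phi_T = w_center * fix.phi_center[0] + w_leaf * fix.phi_leaf[1]
    tau_T = w_center * fix.tau_center[0] + w_leaf * fix.tau_leaf[1]
    tau_ext_T = w_center * ext.tau_center[0] + w_leaf * ext.tau_leaf[1]
    return AbsorptionSummary(
        fixation_prob=np.stack([fix.phi_center, fix.phi_leaf]),
        cond_fixation_time=np.stack([fix.tau_center, fix.tau_leaf]),
        extinction_prob=np.stack([ext.phi_center, ext.phi_leaf]),
        cond_extinction_time=np.stack([ext.tau_center, ext.tau_leaf]),
        phi_T=float(phi_T),
        tau_T=float(tau_T),
        tau_ext_T=float(tau_ext_T),
        meta={"chain": c},
    )


def star_phi_T(n: int, lam: float, delta: float, r) -> np.ndarray | float:
    """Temperature-initialised fixation probability of the weighted star.

    Closed form, vectorized over the relative fitness ``r`` (used heavily by
    the steady-state quadrature): with ``q = pi_down_leaf / pi_up_center``,
    ``phi_1_center = 1 / A(1, n)`` where ``A(1, n) = 1 + pi_down_center *
    sum_{t=1}^{n-1} q^t``, and the center/leaf entry states weigh in as
    ``phi_T = w_center * pi_up_center * phi_1_center
    + w_leaf * pi_up_leaf * phi_1_center``.
    """
    r = np.asarray(r, dtype=float)
    scalar = r.ndim == 0
    r = np.atleast_1d(r)
    if np.any(r <= 0):
        raise ValueError("relative fitness must be positive")
    pi_up_c = r * delta / (n * lam + r * delta)
    pi_down_c = 1.0 - pi_up_c
    pi_up_l = n * lam * r / (n * lam * r + delta)
    pi_down_l = 1.0 - pi_up_l
    q = pi_down_l / pi_up_c
    m = n - 1  # number of geometric terms
    with np.errstate(over="ignore"):
        geom = np.where(
            np.abs(q - 1.0) < 1e-12, float(m), q * np.expm1(m * np.log(q)) / (q - 1.0)
        )
    phi_1c = 1.0 / (1.0 + pi_down_c * geom)
    w_center = (1.0 - delta + n * lam) / (n + 1)
    w_leaf = n * (delta / n + 1.0 - lam) / (n + 1)
    phi = w_center * pi_up_c * phi_1c + w_leaf * pi_up_l * phi_1c
    return float(phi[0]) if scalar else phi


def star_neutral_closed_forms(n: int, lam: float, delta: float) -> dict[str, float]:
    """Neutral (``r = 1``) closed forms for the self-looped weighted star.

    ``tau_0_center = n^4 (n^2 - 1) / [(delta + n lam)(delta + n^2 lam)]
    + n (n + 1) H_n / (delta + n lam)`` and
    ``tau_1_leaf = tau_0_center + (n^2 - 1)/(delta + n lam)``;
    the temperature-initialised time applies the usual weights.
    """
    if n < 2:
        raise ValueError("need at least 2 leaves")
    Hn = harmonic_number(n)
    a = delta + n * lam
    b = delta + n**2 * lam
    tau_0c = n**4 * (n**2 - 1) / (a * b) + n * (n + 1) * Hn / a
    tau_1l = tau_0c + (n**2 - 1) / a
    w_center = (1 - delta + n * lam) / (n + 1)
    w_leaf = n * (delta / n + 1 - lam) / (n + 1)
    tau_T = w_center * tau_0c + w_leaf * tau_1l
    return {"tau_0_center": tau_0c, "tau_1_leaf": tau_1l, "tau_T": tau_T}


def star_neutral_tau_T_closed(n: int, variant: Literal["selflooped_weighted", "star"]) -> float:
    """Fully reduced neutral ``tau_T`` at the two canonical parameter points.

    ``selflooped_weighted``: ``lam = 1/n, delta = 1/n^2`` (scales as n^5);
    ``star``: ``lam = delta = 1`` (scales as n^3).
    """
    Hn = harmonic_number(n)
    if variant == "selflooped_weighted":
        num = (n - 1) * ((n * (n**4 + n - 2) + 2) * n**3 - n + 1) + (n**6 + n**3) * Hn
        den = ((n - 1) * n + 1) * (n**2 + 1)
        return num / den
    if variant == "star":
        return (n - 1) * (n**5 + n**4 + n**2 + 1) / ((n + 1) * (n**2 + 1)) + n * Hn
    raise ValueError(f"unknown variant {variant!r}")


# ---------------------------------------------------------------------------
# birth-death chains (complete graph, cycle)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BDChain:
    """One-dimensional birth-death chain on the mutant count ``i = 0..N``.

    ``T_plus[i-1]`` / ``T_minus[i-1]`` are the per-Moran-step probabilities
    to go from ``i`` to ``i + 1`` / ``i - 1`` mutants, for ``i = 1..N-1``.
    """

    N: int
    T_plus: np.ndarray
    T_minus: np.ndarray
    family_tag: str | None = None

    def __post_init__(self) -> None:
        tp = np.asarray(self.T_plus, dtype=float)
        tm = np.asarray(self.T_minus, dtype=float)
        if tp.shape != (self.N - 1,) or tm.shape != (self.N - 1,):
            raise ValueError("T_plus/T_minus must have length N - 1")
        if np.any(tp < 0) or np.any(tm < 0) or np.any(tp + tm > 1 + 1e-12):
            raise ValueError("transition probabilities must lie in [0, 1] with sum <= 1")
        object.__setattr__(self, "T_plus", tp)
        object.__setattr__(self, "T_minus", tm)

    def gamma(self) -> np.ndarray:
        """``gamma_i = T_i- / T_i+`` for ``i = 1..N-1``."""
        with np.errstate(divide="ignore"):
            return self.T_minus / self.T_plus


def family_chain(family: Literal["complete", "cycle"], N: int, r: float) -> BDChain:
    """Birth-death chain for the complete graph or the cycle.

    Complete: ``T_i- = (N-i)/(ir+N-i) * i/(N-1)``,
    ``T_i+ = ir/(ir+N-i) * (N-i)/(N-1)``.
    Cycle: ``T_i- = 1/(ir+N-i)``, ``T_i+ = r/(ir+N-i)``.
    Both are isothermal, so they share ``gamma_i = 1/r`` and hence the same
    fixation probabilities at equal ``r``.
    """
    if N < 2:
        raise ValueError("N must be at least 2")
    if r <= 0:
        raise ValueError("relative fitness must be positive")
    i = np.arange(1, N)
    tot = i * r + N - i
    if family == "complete":
        T_minus = (N - i) / tot * i / (N - 1)
        T_plus = i * r / tot * (N - i) / (N - 1)
    elif family == "cycle":
        T_minus = 1.0 / tot
        T_plus = r / tot
    else:
        raise ValueError(f"unknown isothermal family {family!r}")
    return BDChain(N=N, T_plus=T_plus, T_minus=T_minus, family_tag=f"{family}(N={N}, r={r})")


def _bd_phi(c: BDChain) -> np.ndarray:
    """Fixation probabilities ``phi_i``, ``i = 0..N`` (log-space products)."""
    N = c.N
    log_gamma = np.log(c.gamma())
    # log of cumulative products Prod_{l=1}^k gamma_l, k = 1..N-1
    log_cum = np.cumsum(log_gamma)
    # phi_i = (1 + sum_{k=1}^{i-1} prod) / (1 + sum_{k=1}^{N-1} prod)
    terms = np.concatenate([[0.0], log_cum])  # k = 0..N-1 with the leading 1
    log_den = logsumexp(terms)
    phi = np.empty(N + 1)
    phi[0] = 0.0
    for i in range(1, N + 1):
        phi[i] = np.exp(logsumexp(terms[:i]) - log_den)
    phi[N] = 1.0
    return phi


def _bd_conditional_times(c: BDChain, phi: np.ndarray) -> np.ndarray:
    """Conditional mean absorption times from the tridiagonal psi-system."""
    N = c.N
    tot = c.T_plus + c.T_minus
    t = 1.0 / tot
    pi_plus = c.T_plus * t
    pi_minus = c.T_minus * t
    # unknowns psi_1..psi_{N-1}; psi_0 = psi_N = 0
    ab = np.zeros((3, N - 1))
    ab[0, 1:] = -pi_plus[:-1]  # superdiagonal
    ab[1, :] = 1.0
    ab[2, :-1] = -pi_minus[1:]  # subdiagonal
    rhs = phi[1:N] * t
    psi = solve_banded((1, 1), ab, rhs)
    with np.errstate(divide="ignore", invalid="ignore"):
        tau = np.full(N + 1, np.nan)
        inner = np.where(phi[1:N] > 0, psi / np.where(phi[1:N] > 0, phi[1:N], 1.0), np.nan)
        tau[1:N] = inner
    tau[0] = 0.0 if phi[0] > 0 else np.nan
    tau[N] = 0.0 if phi[N] > 0 else np.nan
    return tau


def bd_chain_absorption(c: BDChain) -> AbsorptionSummary:
    """Exact absorption summary for a birth-death chain.

    Fixation probabilities use the classical gamma-product formula
    (log-space); conditional fixation and extinction times solve the
    tridiagonal conditional-time systems, which reproduce the familiar
    nested-sum expressions exactly.  If some ``T_i+ = 0`` the chain cannot
    fix from states at or below ``i``; those entries are NaN and the chain
    is reported as extinction-only.
    """
    if np.any(c.T_plus == 0):
        phi = np.zeros(c.N + 1)
        phi[c.N] = 1.0
        ext = 1.0 - phi
        tau = np.full(c.N + 1, np.nan)
        tau_ext = _bd_conditional_times(c, ext)
        return AbsorptionSummary(phi, tau, ext, tau_ext, meta={"extinction_only": True})
    phi = _bd_phi(c)
    ext = 1.0 - phi
    tau = _bd_conditional_times(c, phi)
    tau_ext = _bd_conditional_times(c, ext)
    # isothermal: a single fresh mutant is state i = 1 for every init scheme
    return AbsorptionSummary(
        fixation_prob=phi,
        cond_fixation_time=tau,
        extinction_prob=ext,
        cond_extinction_time=tau_ext,
        phi_T=float(phi[1]),
        tau_T=float(tau[1]),
        tau_ext_T=float(tau_ext[1]),
        meta={"chain": c},
    )


def complete_fixation_prob(f_mut, f_wt, N: int):
    """Moran Bd fixation probability of one mutant on the complete graph.

    ``phi = (1 - f/f') / (1 - (f/f')^N)`` with the neutral limit ``1/N``;
    evaluated via ``expm1`` in log space so it is stable for large ``N``
    and extreme fitness ratios.  Vectorized over ``f_mut`` and ``f_wt``.
    """
    if N < 2:
        raise ValueError("N must be at least 2")
    f_mut = np.asarray(f_mut, dtype=float)
    f_wt = np.asarray(f_wt, dtype=float)
    if np.any(f_mut <= 0) or np.any(f_wt <= 0):
        raise ValueError("fitness values must be positive")
    x = np.log(f_wt) - np.log(f_mut)  # log of f/f'
    x = np.atleast_1d(x)
    out = np.empty_like(x)
    neutral = np.abs(np.expm1(x)) < _NEUTRAL_TOL
    out[neutral] = 1.0 / N
    pos = ~neutral & (x > 0)  # deleterious mutant: exp(Nx) may overflow
    out[pos] = np.expm1(x[pos]) * np.exp(-N * x[pos]) / (-np.expm1(-N * x[pos]))
    neg = ~neutral & (x < 0)
    out[neg] = np.expm1(x[neg]) / np.expm1(N * x[neg])
    return out if out.shape != (1,) else float(out[0])


# ---------------------------------------------------------------------------
# self-looped directed line
# ---------------------------------------------------------------------------


@dataclass
class DirectedLineTimes:
    """Absorption times on the self-looped directed line (root = node 0).

    ``tau_fix`` is exact and independent of the initialisation scheme (only
    a root-seeded mutant can fix, and then the mutant count can only grow).
    ``tau_ext_per_node[alpha]`` (``alpha = 1..N-1``) is the stated
    high-fitness approximation: the mutant block grows until the terminal
    node is reached, then shrinks from the left.  ``tau_ext_T`` weights the
    per-node times by node temperature over the non-root nodes.
    """

    N: int
    r: float
    tau_fix: float
    tau_ext_per_node: np.ndarray
    tau_ext_T: float
    approximation: str = "extinction times assume f'/f >> 1"


def directed_line_times(N: int, r: float) -> DirectedLineTimes:
    """Fixation/extinction times for the self-looped directed line.

    ``tau_1 = sum_{k=1}^{N-1} 2 (k r + N - k)/r = N (N - 1)(1 + 1/r)``;
    ``tau_ext(alpha) = N - 1 - alpha + sum_{j=1}^{alpha} 2 (j r + N - j)``.
    """
    if N < 2:
        raise ValueError("N must be at least 2")
    if r <= 0:
        raise ValueError("relative fitness must be positive")
    k = np.arange(1, N)
    tau_fix = float(np.sum(2.0 * (k * r + N - k) / r))

    alphas = np.arange(1, N)
    # sum_{j=1}^{alpha} 2 (j r + N - j), vectorized via cumulative sums
    j = np.arange(1, N)
    shrink = np.cumsum(2.0 * (j * r + N - j))
    tau_ext = (N - 1 - alphas) + shrink

    # temperatures of the non-root nodes of the self-looped directed line:
    # 1 for bulk nodes, 3/2 for the terminal node (1/2 incoming + own loop)
    temps = np.ones(N - 1)
    temps[-1] = 1.5
    tau_ext_T = float(np.sum(temps * tau_ext) / np.sum(temps))
    return DirectedLineTimes(N=N, r=r, tau_fix=tau_fix, tau_ext_per_node=tau_ext, tau_ext_T=tau_ext_T)
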