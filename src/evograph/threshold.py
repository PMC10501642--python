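"""Mutation-rate threshold and fixation-time scaling exponents.

The weak-mutation (one-mutant-at-a-time) picture holds while the expected
gap between successive mutations, ``1/mu``, exceeds the time a mutant needs
to either fix or die out.  The threshold estimate is therefore

    1/mu_th  ~  max_r { tau_T(r), tau_ext_T(r) }

with the maximum taken over the achievable relative fitness values
``r = f'/f`` in the fitness domain, ``[f_min/f_max, f_max/f_min]``.  For
the star, complete and cycle families the maximum sits at the fixation
branch near neutrality; for the self-looped directed line the fixation
time grows monotonically as ``r`` decreases, so the smallest achievable
``r`` dominates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .chains import (
    bd_chain_absorption,
    directed_line_times,
    family_chain,
    star_chain,
    star_temperature_summary,
)

__all__ = ["ThresholdResult", "mu_threshold", "tau_T_functions", "scaling_exponent"]

_THRESHOLD_FAMILIES = (
    "complete",
    "cycle",
    "star",
    "selflooped_weighted_star",
    "selflooped_directed_line",
)


@dataclass
class ThresholdResult:
    """``mu_th`` plus where/on which branch the maximum was attained."""

    mu_th: float
    argmax_r: float
    dominating_branch: str  # "fixation" | "extinction"
    r_grid: np.ndarray
    tau_fix: np.ndarray
    tau_ext: np.ndarray
    family: str
    N: int
    meta: dict = field(default_factory=dict)


def tau_T_functions(
    family: str, N: int, params: dict | None = None
) -> tuple[Callable[[float], float], Callable[[float], float]]:
    """Exact ``tau_T(r)`` and ``tau_ext_T(r)`` for a supported family."""
    params = dict(params or {})
    n = N - 1
    if family in ("complete", "cycle"):

        def tau(r: float, _fam=family) -> float:
            return bd_chain_absorption(family_chain(_fam, N, r)).tau_T

        def tau_ext(r: float, _fam=family) -> float:
            return bd_chain_absorption(family_chain(_fam, N, r)).tau_ext_T

        return tau, tau_ext
    if family in ("star", "selflooped_weighted_star"):
        if family == "star":
            lam, delta = 1.0, 1.0
        else:
            lam = float(params.get("lam", 1.0 / n))
            delta = float(params.get("delta", 1.0 / n**2))

        def tau(r: float) -> float:
            return star_temperature_summary(star_chain(n, lam, delta, r)).tau_T

        def tau_ext(r: float) -> float:
            return star_temperature_summary(star_chain(n, lam, delta, r)).tau_ext_T

        return tau, tau_ext
    if family == "selflooped_directed_line":

        def tau(r: float) -> float:
            return directed_line_times(N, r).tau_fix

        def tau_ext(r: float) -> float:
            return directed_line_times(N, r).tau_ext_T

        return tau, tau_ext
    raise ValueError(f"unsupported family {family!r}; choose from {_THRESHOLD_FAMILIES}")


def mu_threshold(
    family: str,
    N: int,
    f_min: float,
    f_max: float,
    r_grid_size: int = 101,
    params: dict | None = None,
) -> ThresholdResult:
    """Estimate the mutation-rate threshold for a graph family.

    Evaluates the exact conditional fixation and extinction times on a
    log-spaced grid of relative fitness values spanning the achievable
    range and returns the reciprocal of the overall maximum.
    """
    if not (0.0 < f_min < f_max):
        raise ValueError("need 0 < f_min < f_max")
    r_grid = np.logspace(np.log10(f_min / f_max), np.log10(f_max / f_min), r_grid_size)
    tau_fn, tau_ext_fn = tau_T_functions(family, N, params)
    tau_fix = np.array([tau_fn(float(r)) for r in r_grid])
    tau_ext = np.array([tau_ext_fn(float(r)) for r in r_grid])
    stacked = np.stack([tau_fix, tau_ext])
    branch_idx, r_idx = np.unravel_index(np.nanargmax(stacked), stacked.shape)
    t_max = float(stacked[branch_idx, r_idx])
    return ThresholdResult(
        mu_th=1.0 / t_max,
        argmax_r=float(r_grid[r_idx]),
        dominating_branch="fixation" if branch_idx == 0 else "extinction",
        r_grid=r_grid,
        tau_fix=tau_fix,
        tau_ext=tau_ext,
        family=family,
        N=N,
        meta={"f_min": f_min, "f_max": f_max},
    )


def scaling_exponent(
    times_fn: Callable[[int], float], N_values: Sequence[int]
) -> tuple[float, int]:
    """Least-squares log-log slope of a fixation-time law against ``N``.

    Returns the raw slope and its nearest-integer rounding (the advertised
    contract for the scaling tables).
    """
    N_values = np.asarray(sorted(N_values), dtype=float)
    if N_values.size < 3:
        raise ValueError("need at least 3 population sizes")
    times = np.array([times_fn(int(N)) for N in N_values], dtype=float)
    if np.any(~np.isfinite(times)) or np.any(times <= 0):
        raise ValueError("fixation times must be positive and finite")
    slope = float(np.polyfit(np.log(N_values), np.log(times), 1)[0])
    return slope, int(round(slope))
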