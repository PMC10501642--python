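"""Mutant-fitness kernels.

When a reproduction event mutates (probability ``mu``), the offspring
fitness ``f'`` is drawn from a kernel density ``zeta(f', f)`` supported on
the closed fitness domain ``[f_min, f_max]``, with ``f`` the parent's
fitness.  Two kernels are provided:

* ``uniform`` -- ``zeta = 1/(f_max - f_min)``, independent of the parent;
* ``truncated_gaussian`` -- a Gaussian of mean ``f`` and standard deviation
  ``sigma``, renormalized by its mass on the domain (samples at the bounds
  are kept; nothing is clipped or rejected out of the stated density).

The density *ratio* ``zeta(a, b)/zeta(b, a)`` is what the detailed-balance
steady states need.  For the truncated Gaussian the exponents cancel by
symmetry of ``|a - b|``, leaving the ratio of truncation masses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.stats import truncnorm, uniform as _uniform_dist

__all__ = ["MutationKernel", "kernel_from_spec"]


@dataclass(frozen=True)
class MutationKernel:
    """Mutant fitness distribution ``zeta(f', f)`` on ``[f_min, f_max]``."""

    kind: str
    f_min: float
    f_max: float
    sigma: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "truncated_gaussian"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if not (0.0 < self.f_min < self.f_max):
            raise ValueError("fitness domain requires 0 < f_min < f_max")
        if self.kind == "truncated_gaussian":
            if self.sigma is None or self.sigma <= 0:
                raise ValueError("truncated_gaussian needs sigma > 0")

    # -- helpers ---------------------------------------------------------
    @property
    def width(self) -> float:
        return self.f_max - self.f_min

    def _check_domain(self, *values) -> None:
        for v in values:
            arr = np.asarray(v, dtype=float)
            if arr.size and (arr.min() < self.f_min - 1e-12 or arr.max() > self.f_max + 1e-12):
                raise ValueError(
                    f"fitness value outside the domain [{self.f_min}, {self.f_max}]"
                )

    def _mass(self, mean):
        """Gaussian mass of N(mean, sigma^2) on the fitness domain."""
        from scipy.special import ndtr

        mean = np.asarray(mean, dtype=float)
        s = self.sigma
        return ndtr((self.f_max - mean) / s) - ndtr((self.f_min - mean) / s)

    # -- public surface --------------------------------------------------
    def density(self, f_offspring, f_parent):
        """Evaluate ``zeta(f_offspring, f_parent)``; vectorized."""
        self._check_domain(f_offspring, f_parent)
        f_off = np.asarray(f_offspring, dtype=float)
        f_par = np.asarray(f_parent, dtype=float)
        if self.kind == "uniform":
            out = np.broadcast_arrays(f_off, f_par)[0]
            res = np.full_like(out, 1.0 / self.width, dtype=float)
        else:
            s = self.sigma
            z = np.exp(-0.5 * ((f_off - f_par) / s) ** 2) / (s * np.sqrt(2.0 * np.pi))
            res = z / self._mass(f_par)
        return res if res.ndim else float(res)

    def sample(self, f_parent: float, rng: np.random.Generator, size=None):
        """Draw offspring fitness values given the parent's fitness."""
        self._check_domain(f_parent)
        if self.kind == "uniform":
            draws = rng.uniform(self.f_min, self.f_max, size=size)
        else:
            a = (self.f_min - f_parent) / self.sigma
            b = (self.f_max - f_parent) / self.sigma
            draws = truncnorm.rvs(
                a, b, loc=f_parent, scale=self.sigma, size=size, random_state=rng
            )
        return draws

    def ratio(self, f_a: float, f_b: float) -> float:
        """``zeta(f_a, f_b) / zeta(f_b, f_a)``.

        Exactly 1 for the uniform kernel; for the truncated Gaussian the
        Gaussian factors cancel and only the truncation masses remain.
        """
        self._check_domain(f_a, f_b)
        if self.kind == "uniform":
            return 1.0
        return float(self._mass(f_b) / self._mass(f_a))

    def cdf(self, f, f_parent):
        """Kernel CDF in the offspring argument (used by distribution tests)."""
        self._check_domain(f, f_parent)
        if self.kind == "uniform":
            return _uniform_dist.cdf(f, loc=self.f_min, scale=self.width)
        a = (self.f_min - f_parent) / self.sigma
        b = (self.f_max - f_parent) / self.sigma
        return truncnorm.cdf(f, a, b, loc=f_parent, scale=self.sigma)


def kernel_from_spec(spec: Mapping | MutationKernel) -> MutationKernel:
    """Accept ``{"kind": ..., "f_min": ..., "f_max": ..., "sigma": ...}``."""
    if isinstance(spec, MutationKernel):
        return spec
    spec = dict(spec)
    return MutationKernel(
        kind=spec["kind"],
        f_min=float(spec["f_min"]),
        f_max=float(spec["f_max"]),
        sigma=float(spec["sigma"]) if spec.get("sigma") is not None else None,
    )
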