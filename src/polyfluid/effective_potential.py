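"""Generalized Lennard-Jones effective potential for a crowded polyelectrolyte.

The competition between the short-range electrostatic stretching force F1
and the long-range entropic compressing force F2 acting on a small
polyelectrolyte is summarized by

    V(r) = a * eps * [ (sigma/r)**m - (sigma/r)**n ],     m > n > 0

where ``r`` is the end-to-end extent of the chain, ``sigma`` the extent at
which the two contributions cancel (V = 0) and ``eps`` the energy scale.
The prefactors a = beta**m and b = beta**(m-n) make the two
parameterizations pointwise identical:

    V(r) = eps * [ (r_m/r)**m - b*(r_m/r)**n ],     r_m = beta*sigma.

With this normalization the well depth is V(r_m) = -(m/n - 1)*eps, which
equals -eps exactly on the classic family m = 2n (e.g. 12/6, where a = 4
and b = 2); for other exponent pairs eps remains the energy scale but not
the literal depth.

The compression factor beta = (m/n)**(1/(m-n)) > 1 is the model's measure of
crowding-induced size change: sigma is the compressed size under osmotic
pressure, beta*sigma the relaxed size without crowding.

Sign convention (following the force-balance reading of the potential):
F1, the repulsive/stretching component, is reported negative; F2, the
attractive/compressing component, positive; their sum equals dV/dr, so it
vanishes at r_m, is negative (net expansion) for r < r_m and positive
(net compression) for r > r_m.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PotentialParams",
    "ForceDecomposition",
    "potential",
    "potential_b_form",
    "equilibrium_separation",
    "compression_factor",
    "force_decomposition",
    "ellipsoid_force_ratio",
]


def compression_factor(m: float, n: float) -> float:
    """beta = (m/n)**(1/(m-n)); requires m > n > 0.

    Always > 1 when m > n: the relaxed chain (r_m = beta*sigma) is larger
    than the crowded one (sigma), i.e. crowding compresses the chain.
    Continuous in the m -> n limit, where beta -> e**(1/n).
    """
    if not (m > n > 0):
        raise ValueError(f"exponents must satisfy m > n > 0 (got m={m}, n={n})")
    return (m / n) ** (1.0 / (m - n))


@dataclass(frozen=True)
class PotentialParams:
    """(eps, sigma, m, n) of the generalized potential with derived a, b, beta, r_m."""

    epsilon: float = 1.0
    sigma: float = 1.0
    m: float = 12.0
    n: float = 6.0

    def __post_init__(self) -> None:
        if not self.epsilon > 0:
            raise ValueError(f"energy scale epsilon must be positive (got {self.epsilon})")
        if not self.sigma > 0:
            raise ValueError(f"zero-crossing sigma must be positive (got {self.sigma})")
        compression_factor(self.m, self.n)  # validates m > n > 0

    @property
    def beta(self) -> float:
        return compression_factor(self.m, self.n)

    @property
    def a(self) -> float:
        """Prefactor of the (sigma/r) form; a = beta**m (the classic 4 at m=12, n=6)."""
        return self.beta ** self.m

    @property
    def b(self) -> float:
        """Prefactor of the (r_m/r) form; b = beta**(m-n)."""
        return self.beta ** (self.m - self.n)

    @property
    def r_m(self) -> float:
        return equilibrium_separation(self)

    @property
    def depth(self) -> float:
        """Well depth |V(r_m)| = (m/n - 1)*epsilon; equals epsilon when m = 2n."""
        return (self.m / self.n - 1.0) * self.epsilon


def _check_r(r):
    r = np.asarray(r, dtype=float)
    if (r <= 0).any():
        raise ValueError("separation r must be positive")
    return r


def potential(params: PotentialParams, r):
    """V(r) = a*eps*[(sigma/r)**m - (sigma/r)**n]; accepts scalar or array r."""
    r = _check_r(r)
    x = params.sigma / r
    v = params.a * params.epsilon * (x ** params.m - x ** params.n)
    return float(v) if v.ndim == 0 else v


def potential_b_form(params: PotentialParams, r):
    """Equivalent parameterization V(r) = eps*[(r_m/r)**m - b*(r_m/r)**n]."""
    r = _check_r(r)
    x = params.r_m / r
    v = params.epsilon * (x ** params.m - params.b * x ** params.n)
    return float(v) if v.ndim == 0 else v


def equilibrium_separation(params: PotentialParams) -> float:
    """r_m = (m/n)**(1/(m-n)) * sigma, the minimum of the potential.

    The depth there is V(r_m) = -(m/n - 1)*eps (-eps on the m = 2n family).
    """
    return compression_factor(params.m, params.n) * params.sigma


@dataclass(frozen=True)
class ForceDecomposition:
    """Signed components of the effective force at extent r.

    ``F1 < 0`` is the short-range repulsive (stretching) contribution,
    ``F2 > 0`` the long-range attractive (compressing) one; ``F1 + F2``
    equals dV/dr and vanishes at the equilibrium extent.
    """

    F1: float
    F2: float
    r: float

    @property
    def net(self) -> float:
        return self.F1 + self.F2


def force_decomposition(params: PotentialParams, r: float) -> ForceDecomposition:
    """Split dV/dr into the repulsive (F1 < 0) and attractive (F2 > 0) parts."""
    r = float(_check_r(r))
    ae = params.a * params.epsilon
    f1 = -ae * params.m * params.sigma ** params.m / r ** (params.m + 1)
    f2 = ae * params.n * params.sigma ** params.n / r ** (params.n + 1)
    return ForceDecomposition(F1=f1, F2=f2, r=r)


def ellipsoid_force_ratio(d: float, c: float, literal: bool = False) -> float:
    """Force ratio F1/F2 for a chain shaped as a prolate ellipsoid.

    ``d`` is the long semi-axis, ``c`` the two equal short semi-axes
    (0 < c <= d).  The scale-invariant form

        F1/F2 = 1 - 2d / sqrt(d**2 + c**2)

    gives the sphere value 1 - sqrt(2) = -0.41 at c = d and -0.79 at
    c = d/2: the stretching force grows relative to the compressing one as
    the shape elongates, feeding the loss of symmetry.  ``literal=True``
    evaluates the non-scale-invariant variant 1 - 2d/(d**2 + c**2), kept
    only for auditability; it reproduces the anchor values solely at d = 1.
    """
    if not (d > 0 and 0 < c <= d):
        raise ValueError(f"axes must satisfy 0 < c <= d (got d={d}, c={c})")
    if literal:
        return 1.0 - 2.0 * d / (d * d + c * c)
    return 1.0 - 2.0 * d / math.hypot(d, c)
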