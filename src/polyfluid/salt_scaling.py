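"""Salt-dependent scaling of the radius of gyration of a small polyelectrolyte.

A short single-stranded DNA homopolymer (a "pT") in a salt solution obeys
the scaling relation

    Rg(s, N, P) = A0(s) * N**nu(s) * F(s, N, P)

where ``s`` is the NaCl concentration in mM, ``N`` the number of monomers,
``P`` the crowding percentage and ``F`` the crowding deformation factor
(``F == 1`` at ``P == 0`` by definition).  The effective monomer length
``A0`` and the stiffness exponent ``nu`` are linear in ``y = log10(s/1 mM)``,
calibrated against experimental data:

    A0(s) = 11/4 + y/4        (Angstrom)
    nu(s) = 0.794 - 0.0674*y

Salt screens the electrostatic repulsion between the charged monomers, so
the chain softens with increasing ``s``: ``nu`` falls from ~0.8 (stiff,
rope-leaning) toward the ideal-chain value 1/2 at molar concentrations.
Because the experimental ``A0`` is noisy at the monomer scale, ``A0`` is
conventionally normalized to 1, which is the default for all derived
quantities in this package.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "NU_MIN",
    "NU_MAX",
    "SaltConditions",
    "ScalingQuery",
    "monomer_length",
    "scaling_exponent",
    "rg_scaling",
    "fit_scaling",
    "crowding_factor_from_potential",
]

#: Physical bounds of the stiffness exponent: 1/3 for a collapsed globule
#: (poor solvent), 1 for a rigid rope of aligned monomers.
NU_MIN = 1.0 / 3.0
NU_MAX = 1.0


def _check_salt(s: float) -> float:
    s = float(s)
    if not s > 0:
        raise ValueError(f"salt concentration must be positive (got {s} mM)")
    return s


def monomer_length(s: float, normalized: bool = False) -> float:
    """Effective monomer length A0(s) = 11/4 + log10(s)/4, in Angstrom.

    ``s`` is in mM.  With ``normalized=True`` returns exactly 1, the
    convention used for every polymer-scale quantity downstream.
    """
    s = _check_salt(s)
    if normalized:
        return 1.0
    return 11.0 / 4.0 + math.log10(s) / 4.0


def scaling_exponent(s: float, clamp: bool = True) -> float:
    """Stiffness exponent nu(s) = 0.794 - 0.0674*log10(s), s in mM.

    The linear form is a fit over 1 mM <= s <= 20 M; outside that range it is
    extrapolated and, with ``clamp=True`` (default), confined to the physical
    interval [1/3, 1] with a warning.
    """
    s = _check_salt(s)
    nu = 0.794 - 0.0674 * math.log10(s)
    if clamp and not (NU_MIN <= nu <= NU_MAX):
        warnings.warn(
            f"nu({s} mM) = {nu:.4f} outside [1/3, 1]; clamped to the "
            "physical globule/rope bounds",
            stacklevel=2,
        )
        nu = min(max(nu, NU_MIN), NU_MAX)
    return nu


@dataclass(frozen=True)
class SaltConditions:
    """Salt concentration and the scaling parameters it determines.

    Attributes
    ----------
    s : float
        NaCl concentration in mM (positive).
    normalized : bool
        If True (default), ``A0`` is forced to 1.
    """

    s: float
    normalized: bool = True

    def __post_init__(self) -> None:
        _check_salt(self.s)

    @property
    def y(self) -> float:
        """log10 of the salt concentration in mM."""
        return math.log10(self.s)

    @property
    def A0(self) -> float:
        return monomer_length(self.s, normalized=self.normalized)

    @property
    def nu(self) -> float:
        return scaling_exponent(self.s)


@dataclass(frozen=True)
class ScalingQuery:
    """A (N, P, F) query against the scaling law.

    ``F`` may be a number or a callable ``F(s, N, P)``; it defaults to the
    no-crowding boundary value 1.  At ``P == 0`` the deformation factor must
    be 1 by definition.
    """

    N: int
    P: float = 0.0
    F: float | Callable[[float, int, float], float] = 1.0

    def __post_init__(self) -> None:
        if int(self.N) != self.N or self.N < 1:
            raise ValueError(f"monomer count N must be an integer >= 1 (got {self.N})")
        if not 0.0 <= self.P <= 100.0:
            raise ValueError(f"crowding percentage P must lie in [0, 100] (got {self.P})")

    def deformation(self, s: float) -> float:
        f = self.F(s, self.N, self.P) if callable(self.F) else float(self.F)
        if not f > 0:
            raise ValueError(f"deformation factor must be positive (got {f})")
        if self.P == 0.0 and not math.isclose(f, 1.0):
            raise ValueError(
                f"P = 0 requires F = 1 (boundary condition of the scaling law); got {f}"
            )
        return f


def rg_scaling(cond: SaltConditions, query: ScalingQuery) -> float:
    """Radius of gyration Rg = A0(s) * N**nu(s) * F(s, N, P)."""
    return cond.A0 * float(query.N) ** cond.nu * query.deformation(cond.s)


def crowding_factor_from_potential(m: float, n: float) -> float:
    """Deformation factor F = 1/beta from the effective-potential compression.

    ``beta = (m/n)**(1/(m-n)) > 1`` measures how much crowding compresses the
    chain relative to its uncrowded size, so the crowded Rg is the uncrowded
    one divided by beta.
    """
    from .effective_potential import compression_factor

    return 1.0 / compression_factor(m, n)


def fit_scaling(pairs: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Least-squares (A0, nu) from (N, Rg) pairs via log Rg = log A0 + nu log N.

    Requires at least two distinct N values and strictly positive Rg.
    Returns ``(A0_hat, nu_hat)``.
    """
    if len(pairs) < 2:
        raise ValueError("need at least two (N, Rg) pairs")
    N = np.asarray([p[0] for p in pairs], dtype=float)
    rg = np.asarray([p[1] for p in pairs], dtype=float)
    if (N < 1).any():
        raise ValueError("all N must be >= 1")
    if (rg <= 0).any():
        raise ValueError("all Rg must be positive")
    if np.unique(N).size < 2:
        raise ValueError("degenerate design: need at least two distinct N values")
    nu_hat, log_a0 = np.polyfit(np.log(N), np.log(rg), 1)
    return float(np.exp(log_a0)), float(nu_hat)
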