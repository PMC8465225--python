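"""Analytic chain models: wormlike-chain Rg and freely jointed chain relations.

The wormlike (Kratky-Porod) chain interpolates between a flexible coil and a
rigid rod through the persistence length Lp.  Its radius of gyration for
contour length l is

    Rg^2 = l*Lp/3 - Lp^2 + 2*Lp^3/l - (2*Lp^4/l^2) * (1 - exp(-l/Lp))

with the effective monomer length normalized to one, so l = N monomers.
Limits: Lp = 1, l -> inf gives Rg -> sqrt(l/3) (ideal coil); Lp = l -> inf
gives Rg/l -> sqrt(1/3 + 2/e - 1) ~= 0.263, i.e. roughly l/4 (rigid rod-like).

The freely jointed chain (nu = 1/2) obeys Re-e = sqrt(6)*Rg = A0*sqrt(6N),
hence the shape ratio alpha = Rg/Re-e = 1/sqrt(6) ~= 0.408.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "ChainSpec",
    "wormlike_rg",
    "freely_jointed_ree",
    "freely_jointed_alpha",
    "ROD_LIMIT_RATIO",
]

#: Limiting Rg/l of the wormlike chain at maximum stiffness (Lp = l -> inf):
#: sqrt(1/3 - 1 + 2 - 2*(1 - 1/e)).
ROD_LIMIT_RATIO = math.sqrt(4.0 / 3.0 - 2.0 * (1.0 - math.exp(-1.0)))


@dataclass(frozen=True)
class ChainSpec:
    """(N, Lp, l) for the analytic chain models; l defaults to N (unit monomers)."""

    N: int
    Lp: float
    l: float | None = None

    def __post_init__(self) -> None:
        if int(self.N) != self.N or self.N < 1:
            raise ValueError(f"monomer count N must be an integer >= 1 (got {self.N})")
        if self.l is None:
            object.__setattr__(self, "l", float(self.N))
        if not self.l > 0:
            raise ValueError(f"contour length must be positive (got {self.l})")
        if not 0 < self.Lp <= self.l:
            raise ValueError(
                f"persistence length must satisfy 0 < Lp <= l (got Lp={self.Lp}, l={self.l})"
            )


def wormlike_rg(spec: ChainSpec | None = None, *, l: float | None = None,
                Lp: float | None = None) -> float:
    """Wormlike-chain radius of gyration.

    Accepts either a :class:`ChainSpec` or explicit ``l`` and ``Lp`` keywords.
    """
    if spec is not None:
        l, Lp = spec.l, spec.Lp
    if l is None or Lp is None:
        raise TypeError("provide a ChainSpec or both l= and Lp=")
    if not (l > 0 and Lp > 0):
        raise ValueError(f"l and Lp must be positive (got l={l}, Lp={Lp})")
    rg2 = (
        l * Lp / 3.0
        - Lp ** 2
        + 2.0 * Lp ** 3 / l
        - (2.0 * Lp ** 4 / l ** 2) * (1.0 - math.exp(-l / Lp))
    )
    if rg2 <= 0:
        # cannot occur for 0 < Lp <= l; guards pathological inputs
        raise ArithmeticError(
            f"wormlike Rg^2 = {rg2} <= 0 for l={l}, Lp={Lp}; parameters unphysical"
        )
    return math.sqrt(rg2)


def freely_jointed_ree(N: int, A0: float = 1.0) -> float:
    """End-to-end distance of a freely jointed chain: Re-e = A0*sqrt(6N)."""
    if int(N) != N or N < 1:
        raise ValueError(f"monomer count N must be an integer >= 1 (got {N})")
    return A0 * math.sqrt(6.0 * N)


def freely_jointed_alpha() -> float:
    """Shape ratio alpha = Rg/Re-e = 1/sqrt(6) of the freely jointed chain."""
    return 1.0 / math.sqrt(6.0)
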