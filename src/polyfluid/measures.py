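"""Conversions among Rg, Rh and Re-e, shape ratios, and regime classification.

Different experiments see different sizes of the same chain: small-angle
X-ray scattering yields the radius of gyration Rg, diffusion/viscosity the
hydrodynamic radius Rh, and FRET the end-to-end distance Re-e.  This module
implements the conversion conventions used throughout the reference tables:

* ``Rh = sqrt(5*Rg/3)`` -- the (dimensionally loose) table rule that
  generated the tabulated Rh rows; the default.
* ``Rh = (3/5)*Rg`` -- the dimensionally consistent good-solvent rule
  (Rg ~ (5/3)*Rh), available as convention ``"linear"``.
* ``Re-e = 3.1*Rh`` -- the standard-conditions chaining rule.
* compact sphere of N unit monomers: R = N**(1/3), Rg = sqrt(6/5)*R and
  Re-e = 2*R = sqrt(25/6)*Rg/... = 1.8*Rg.

The stiffness exponent nu maps onto named solvent/configuration regimes
(globule 1/3, theta 1/2, SAW 0.588, good solvent 3/5, rigid rope 1); the
classifier snaps a measured nu (or the shape ratio alpha = Rg/Re-e) to the
nearest anchor, with boundaries at midpoints and ties resolved toward the
stiffer regime.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "MeasureSet",
    "rh_from_rg",
    "ree_from_rh",
    "sphere_ree",
    "alpha_factor",
    "classify_regime",
    "measure_pipeline",
    "NU_ANCHORS",
    "ALPHA_ANCHORS",
]

RH_CONVENTIONS = ("sqrt", "linear")

#: (label, nu) anchors, ordered by increasing stiffness.
NU_ANCHORS: tuple[tuple[str, float], ...] = (
    ("sphere", 1.0 / 3.0),
    ("theta", 0.5),
    ("saw", 0.588),
    ("good", 0.6),
    ("rope", 1.0),
)

#: (label, alpha = Rg/Re-e) anchors: rigid rod 1/sqrt(12), random coil
#: 1/sqrt(6), compact sphere 1/1.8; ordered by increasing alpha.
ALPHA_ANCHORS: tuple[tuple[str, float], ...] = (
    ("rope", 1.0 / math.sqrt(12.0)),
    ("theta", 1.0 / math.sqrt(6.0)),
    ("sphere", 1.0 / 1.8),
)


@dataclass(frozen=True)
class MeasureSet:
    """One consistent set of size measures and the Rh convention that made it."""

    Rg: float
    Rh: float
    Ree: float
    alpha: float
    convention: str = "sqrt"

    def __post_init__(self) -> None:
        if min(self.Rg, self.Rh, self.Ree) < 0:
            raise ValueError("all size measures must be non-negative")


def rh_from_rg(Rg: float, convention: str = "sqrt") -> float:
    """Hydrodynamic radius from Rg under the named convention."""
    if Rg < 0:
        raise ValueError(f"Rg must be non-negative (got {Rg})")
    if convention == "sqrt":
        return math.sqrt(5.0 * Rg / 3.0)
    if convention == "linear":
        return 0.6 * Rg
    raise ValueError(f"unknown Rh convention {convention!r}; expected one of {RH_CONVENTIONS}")


def ree_from_rh(Rh: float) -> float:
    """End-to-end distance Re-e = 3.1*Rh (standard-conditions rule)."""
    if Rh < 0:
        raise ValueError(f"Rh must be non-negative (got {Rh})")
    return 3.1 * Rh


def sphere_ree(N: int) -> tuple[float, float]:
    """(Re-e, Re-e/Rg) for a compact sphere of N unit-radius monomers.

    R = N**(1/3) from volume conservation; the chain ends sit at opposite
    poles so Re-e = 2R, and with Rg = sqrt(6/5)*R the ratio is
    2*sqrt(5/6) ~= 1.8, independent of N.
    """
    if int(N) != N or N < 1:
        raise ValueError(f"monomer count N must be an integer >= 1 (got {N})")
    ree = 2.0 * float(N) ** (1.0 / 3.0)
    return ree, 2.0 * math.sqrt(5.0 / 6.0)


def alpha_factor(Rg: float, Ree: float) -> float:
    """Shape ratio alpha = Rg/Re-e."""
    if Ree <= 0:
        raise ValueError(f"Re-e must be positive (got {Ree})")
    return Rg / Ree


def _nearest(anchors: tuple[tuple[str, float], ...], value: float,
             prefer_later: bool = True) -> str:
    # boundaries at midpoints; on an exact midpoint the stiffer regime wins
    # (later entry for the nu anchors, earlier for the alpha anchors)
    best_label, best_dist = anchors[0][0], math.inf
    for label, anchor in anchors:
        d = abs(value - anchor)
        if d < best_dist or (prefer_later and d == best_dist):
            best_label, best_dist = label, d
    return best_label


def classify_regime(nu: float | None = None, alpha: float | None = None) -> str:
    """Map a stiffness exponent nu (or shape ratio alpha) to its nearest regime.

    Exactly one of ``nu`` (in (0, 1.2]) or ``alpha`` (positive) must be
    given.  Regime labels: ``sphere``, ``theta``, ``saw``, ``good``,
    ``rope``.  The anchors are physical; the midpoint boundaries are a
    package convention.
    """
    if (nu is None) == (alpha is None):
        raise ValueError("provide exactly one of nu or alpha")
    if nu is not None:
        if not 0.0 < nu <= 1.2:
            raise ValueError(f"nu must lie in (0, 1.2] (got {nu})")
        return _nearest(NU_ANCHORS, nu, prefer_later=True)
    if not alpha > 0:
        raise ValueError(f"alpha must be positive (got {alpha})")
    return _nearest(ALPHA_ANCHORS, alpha, prefer_later=False)


def measure_pipeline(s: float, N: int, convention: str = "sqrt",
                     normalized: bool = True) -> MeasureSet:
    """Full chain: salt-scaling Rg -> Rh -> Re-e -> alpha for one (s, N)."""
    from .salt_scaling import SaltConditions, ScalingQuery, rg_scaling

    rg = rg_scaling(SaltConditions(s, normalized=normalized), ScalingQuery(N))
    rh = rh_from_rg(rg, convention=convention)
    ree = ree_from_rh(rh)
    return MeasureSet(Rg=rg, Rh=rh, Ree=ree, alpha=alpha_factor(rg, ree),
                      convention=convention)
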