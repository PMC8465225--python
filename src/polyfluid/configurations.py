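"""Coordinate generators for idealized small-polymer configurations.

A chain of N touching hard-sphere monomers of unit radius can be idealized,
in order of decreasing extension, as a straight rope (SR), a planar parabola
or horseshoe (Pa), a sparse sphere (SS), a dense sphere (DS), a ring, or the
more realistic self-avoiding random walk (SAW).  Each generator returns a
:class:`Configuration` of monomer-center coordinates in monomer-radius units
(so touching monomers are 2 units apart), and the generic
:func:`rg_of` computes the radius of gyration

    Rg = sqrt( (1/N) * sum_i |r_i - r_cm|^2 )

with unit monomer masses.  The straight rope and ring have closed forms
(sqrt((N^2-1)/3) and N/(2*pi)) that the generated coordinates reproduce
exactly; the dense sphere is built from concentric shells at radii
0, 2, 4, ... with capacities 1, 7, 19, 37, ... (the centered sequence
3k(k-1)+1), its Rg accounted from the shell radii measured at the sphere
center.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "Configuration",
    "rg_of",
    "straight_rope",
    "ring",
    "shell_structure",
    "dense_sphere",
    "dense_sphere_rg",
    "sparse_sphere",
    "sparse_sphere_rg",
    "parabola",
    "saw_walk",
    "straight_rope_rg",
    "ring_rg",
]

_GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))


@dataclass(frozen=True)
class Configuration:
    """An ordered set of monomer-center coordinates for one idealized shape.

    Coordinates are in monomer-radius units; ``r_mono`` is the monomer
    radius (1 by default, so hard-sphere contact distance is 2).
    """

    coords: np.ndarray
    shape: str
    r_mono: float = 1.0

    def __post_init__(self) -> None:
        coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 1:
            raise ValueError("coords must be a non-empty (N, 3) array")
        object.__setattr__(self, "coords", coords)

    @property
    def N(self) -> int:
        return self.coords.shape[0]

    def min_pair_distance(self) -> float:
        """Smallest pairwise center distance (inf for a single monomer)."""
        if self.N < 2:
            return math.inf
        d = self.coords[:, None, :] - self.coords[None, :, :]
        dist = np.sqrt((d ** 2).sum(-1))
        return float(dist[np.triu_indices(self.N, k=1)].min())

    def to_xyz(self, path: str | Path | None = None, comment: str | None = None) -> str:
        """Standard XYZ text (count / comment / 'C x y z' lines); optionally written to path."""
        buf = StringIO()
        buf.write(f"{self.N}\n")
        buf.write(comment if comment is not None else f"{self.shape} N={self.N} polyfluid")
        buf.write("\n")
        for x, y, z in self.coords:
            buf.write(f"C {x:.8f} {y:.8f} {z:.8f}\n")
        text = buf.getvalue()
        if path is not None:
            Path(path).write_text(text)
        return text


def rg_of(config: Configuration | np.ndarray, center: np.ndarray | None = None) -> float:
    """Root-mean-square distance of the monomer centers from their center of mass.

    ``center`` overrides the centroid (used for shell-accounted spheres where
    the reference point is the sphere center, not the partial-shell centroid).
    """
    coords = config.coords if isinstance(config, Configuration) else np.atleast_2d(
        np.asarray(config, dtype=float)
    )
    if coords.size == 0:
        raise ValueError("empty configuration has no radius of gyration")
    c = coords.mean(axis=0) if center is None else np.asarray(center, dtype=float)
    return float(np.sqrt(((coords - c) ** 2).sum(axis=1).mean()))


# -- straight rope -----------------------------------------------------------

def straight_rope_rg(N: int) -> float:
    """Closed form sqrt((N^2 - 1)/3) for N collinear touching monomers."""
    N = _check_n(N)
    return math.sqrt((N * N - 1) / 3.0)


def straight_rope(N: int) -> Configuration:
    """N collinear monomer centers spaced by one diameter (2 units) along x."""
    N = _check_n(N)
    coords = np.zeros((N, 3))
    coords[:, 0] = 2.0 * np.arange(N)
    return Configuration(coords, shape="SR")


# -- ring --------------------------------------------------------------------

def ring_rg(N: int, perimeter_rule: bool = False) -> float:
    """Ring radius (= Rg, all monomers equidistant from the centroid).

    Default R = N/(2*pi), the convention that reproduces the reference
    values; ``perimeter_rule=True`` uses R = N/pi (perimeter divided by one
    monomer diameter), kept as the alternative geometric reading.
    """
    N = _check_n(N, minimum=3)
    return N / math.pi if perimeter_rule else N / (2.0 * math.pi)


def ring(N: int, perimeter_rule: bool = False) -> Configuration:
    """N centers equally spaced on a circle in the z = 0 plane."""
    R = ring_rg(N, perimeter_rule=perimeter_rule)
    theta = 2.0 * math.pi * np.arange(N) / N
    coords = np.column_stack([R * np.cos(theta), R * np.sin(theta), np.zeros(N)])
    return Configuration(coords, shape="Ring")


# -- dense / sparse spheres --------------------------------------------------

def shell_structure(N: int) -> list[tuple[float, int]]:
    """Concentric-shell occupation [(radius, count), ...] for N monomers.

    Shell k (k = 1, 2, ...) sits at radius 2(k-1) and holds at most
    3k(k-1)+1 monomers (1, 7, 19, 37, 61, ...); the outermost shell takes
    whatever remains.
    """
    N = _check_n(N)
    out: list[tuple[float, int]] = []
    placed, k = 0, 1
    while placed < N:
        cap = 3 * k * (k - 1) + 1
        take = min(cap, N - placed)
        out.append((2.0 * (k - 1), take))
        placed += take
        k += 1
    return out


def dense_sphere_rg(N: int) -> float:
    """Shell-accounted Rg of the dense sphere: sqrt(sum_i n_i r_i^2 / N)."""
    sh = shell_structure(N)
    return math.sqrt(sum(n * r * r for r, n in sh) / N)


def _fibonacci_shell(radius: float, count: int, z_axis_offset: int = 0) -> np.ndarray:
    """Quasi-uniform points on a sphere via the golden-angle spiral."""
    if count == 1:
        return np.array([[0.0, 0.0, radius]]) if radius else np.zeros((1, 3))
    i = np.arange(count, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / count
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    phi = _GOLDEN_ANGLE * (i + z_axis_offset)
    return radius * np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def _shell_coords(shells: list[tuple[float, int]]) -> np.ndarray:
    pts = [_fibonacci_shell(r, n, z_axis_offset=k) for k, (r, n) in enumerate(shells)]
    return np.vstack(pts)


def dense_sphere(N: int) -> Configuration:
    """Concentric-shell dense sphere; shell radii 0, 2, 4, ... capacities 1, 7, 19, 37, ...

    Coordinates place each shell's monomers quasi-uniformly on its sphere, so
    ``rg_of(cfg, center=[0, 0, 0])`` equals :func:`dense_sphere_rg` exactly;
    the centroid-based ``rg_of(cfg)`` differs only through the partial
    outermost shell.
    """
    return Configuration(_shell_coords(shell_structure(N)), shape="DS")


def _sparse_scale(N: int) -> float:
    sh = shell_structure(N)
    r_out = sh[-1][0]
    if r_out == 0.0:
        return 1.0
    # DS enclosing radius is r_out + 1 (outermost centers plus one monomer
    # radius); the sparse sphere dilates so its outermost shell sits one
    # monomer radius beyond that enclosing radius.
    return (r_out + 2.0) / r_out


def sparse_sphere_rg(N: int) -> float:
    """Shell-accounted Rg of the sparse sphere (dilated dense sphere)."""
    return dense_sphere_rg(N) * _sparse_scale(N)


def sparse_sphere(N: int) -> Configuration:
    """Dense-sphere shell structure with radii dilated to the sparse envelope."""
    scale = _sparse_scale(N)
    shells = [(r * scale, n) for r, n in shell_structure(N)]
    return Configuration(_shell_coords(shells), shape="SS")


# -- parabola ----------------------------------------------------------------

def _arc_length(x: float) -> float:
    # arc length of y = x^2 from the apex to x
    return x * math.sqrt(1.0 + 4.0 * x * x) / 2.0 + math.asinh(2.0 * x) / 4.0


def _x_of_arc(s: float) -> float:
    if s == 0.0:
        return 0.0
    hi = max(2.0, math.sqrt(s) + 2.0)
    return brentq(lambda x: _arc_length(x) - s, 0.0, hi, xtol=1e-14)


def parabola(N: int, step: float = 1.0) -> Configuration:
    """N monomer centers at equal arc-length steps along y = x^2, symmetric in x.

    The default step is one monomer length (the chain's contour length is N
    unit monomers); even N places mirror pairs at arc positions
    +/-(k - 1/2)*step, odd N adds the apex monomer.  The x for a given arc
    length is found by numerically inverting the closed-form arc-length
    integral of the parabola.
    """
    N = _check_n(N, minimum=2)
    pts: list[tuple[float, float]] = []
    if N % 2 == 1:
        pts.append((0.0, 0.0))
        arcs = [k * step for k in range(1, (N - 1) // 2 + 1)]
    else:
        arcs = [(k - 0.5) * step for k in range(1, N // 2 + 1)]
    for s in arcs:
        x = _x_of_arc(s)
        pts.append((x, x * x))
        pts.append((-x, x * x))
    coords = np.array([(x, y, 0.0) for x, y in pts])
    return Configuration(coords, shape="Pa")


# -- self-avoiding walk ------------------------------------------------------

def saw_walk(
    N: int,
    seed: int | np.random.Generator,
    max_tries: int = 60,
    max_restarts: int = 20000,
) -> Configuration:
    """Off-lattice self-avoiding chain of N touching unit-radius monomers.

    Each bond has length one diameter and a uniformly random direction; a
    placement overlapping any earlier monomer (center distance < 2) is
    rejected and redrawn up to ``max_tries`` times, after which the whole
    chain restarts.  A fixed integer seed gives bit-identical coordinates.
    """
    N = _check_n(N)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bond = 2.0
    min_d2 = (bond - 1e-9) ** 2
    for _ in range(max_restarts):
        pts = np.zeros((N, 3))
        failed = False
        for i in range(1, N):
            for _t in range(max_tries):
                v = rng.normal(size=3)
                norm = np.linalg.norm(v)
                if norm == 0.0:
                    continue
                cand = pts[i - 1] + bond * v / norm
                if i >= 2:
                    d2 = ((pts[: i - 1] - cand) ** 2).sum(axis=1)
                    if (d2 < min_d2).any():
                        continue
                pts[i] = cand
                break
            else:
                failed = True
                break
        if not failed:
            return Configuration(pts, shape="SAW")
    raise RuntimeError(
        f"self-avoiding walk generation failed after {max_restarts} restarts (N={N})"
    )


def _check_n(N, minimum: int = 1) -> int:
    if int(N) != N or N < minimum:
        raise ValueError(f"monomer count must be an integer >= {minimum} (got {N})")
    return int(N)
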