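# Methods

This note states, in the package's own terms, what each model computes,
the parameter conventions and units, the numerical choices, and the
design decisions that are not obvious from the code.

## Units and conventions

- Salt concentration `s` is in millimolar (mM) throughout; the
  logarithms in the scaling law are base 10 of `s/1 mM`.
- Configuration coordinates use **monomer radii**: monomers are unit
  radius, so touching monomers are 2 units apart.
- Scaling-law and chain-model radii are in **effective monomer
  lengths**: the prefactor `A0` is normalized to 1 by default, so
  `Rg = N^nu`. Passing `normalized=False` (or `--physical-a0`) restores
  the salt-dependent `A0` in Ångström.
- `Rg` is always the root-mean-square distance of monomer centers from
  their center of mass (or from a supplied center, see *Dense sphere*).

## Salt-dependent scaling law

`Rg(s, N, P) = A0(s) · N^nu(s) · F(s, N, P)` with

- `A0(s) = 11/4 + log10(s)/4` (Å), valid for `s` ≥ 0.1 mM (positive
  length);
- `nu(s) = 0.794 − 0.0674·log10(s)`, clamped to `[1/3, 1]` with a
  `RuntimeWarning` outside that interval. The bounds are the compact
  globule (`nu = 1/3`) and the rigid rope (`nu = 1`); values outside
  them have no conformational meaning.
- `F ≡ 1` at `P = 0` (uncrowded boundary condition — constructing a
  `ScalingQuery` with `P = 0` and `F ≠ 1` raises). For `P > 0` the
  deformation factor is caller-supplied, either as a number or a
  callable `F(s, N, P)`. `crowding_factor_from_potential(m, n) = 1/beta`
  provides the potential-derived compression as a convenience.

`fit_scaling` recovers `(A0, nu)` from `(N, Rg)` pairs by ordinary least
squares on `log Rg = log A0 + nu·log N` (`numpy.polyfit`), requiring at
least two distinct `N`. With 1% multiplicative noise and `N = 20…60`
the exponent is recovered to better than ±0.02 (asserted over 1000
replicates in the acceptance suite).

## Effective potential

`V(r) = a·eps·[(sigma/r)^m − (sigma/r)^n]`, `m > n > 0`. The prefactors
`a = beta^m` and `b = beta^(m−n)` with `beta = (m/n)^(1/(m−n))` make
this pointwise identical to `V(r) = eps·[(r_m/r)^m − b·(r_m/r)^n]` with
`r_m = beta·sigma`. Consequences, all asserted by tests:

- `V(sigma) = 0` and `dV/dr(r_m) = 0` for every admissible pair;
- the classic `(12, 6)` case gives `a = 4`, `b = 2`, `r_m = 2^(1/6)·sigma`;
- the well depth is `V(r_m) = −(m/n − 1)·eps`. It equals `−eps` exactly
  on the family `m = 2n` (which contains the classic case); for other
  pairs `eps` is the energy scale, not the literal depth. This is forced
  by the `a = beta^m` normalization: making the depth `eps` for all
  pairs (the Mie normalization) would break the unit-coefficient
  `r_m`-form equivalence above, and we kept the structural relation.
  `PotentialParams.depth` exposes `(m/n − 1)·eps`.

The force split reports `F1 = −a·eps·m·sigma^m/r^(m+1)` (short-range,
stretching, negative) and `F2 = +a·eps·n·sigma^n/r^(n+1)` (long-range,
entropic compression, positive); their sum is `dV/dr`, so the net force
in the usual mechanics convention is its negative. `beta > 1` is the
model's compression factor: `sigma` is the crowded size, `beta·sigma`
the relaxed one. `beta` is continuous as `m → n` (limit `e^(1/n)`).

For a chain idealized as a prolate ellipsoid with long semi-axis `d`
and short semi-axes `c`, the force ratio is
`F1/F2 = 1 − 2d/sqrt(d² + c²)`: −0.41 at `c = d` (sphere) and −0.79 at
`c = d/2`. This form is scale-invariant (depends on `c/d` only), which
a physical shape ratio must be; the non-invariant variant
`1 − 2d/(d² + c²)`, which reproduces the anchors only at `d = 1`, is
kept behind `literal=True` purely for auditability.

## Configuration generators

All generators return a `Configuration` with explicit coordinates, so
every closed-form `Rg` below is cross-checked against the coordinate
calculator `rg_of`.

- **Straight rope (SR).** Centers on a line, spaced one diameter;
  `Rg = sqrt((N² − 1)/3)` in monomer radii.
- **Ring.** `N` monomers equally spaced on a circle of radius
  `R = N/(2π)` (circumference = one radius-unit per monomer); all
  centers are equidistant from the centroid, so `Rg = R` exactly. A
  `perimeter_rule=True` variant uses `R = N/π` (one diameter per
  monomer) for comparison.
- **Dense sphere (DS).** Concentric shells at radii 0, 2, 4, … with
  capacities `3k(k−1) + 1` (1, 7, 19, 37, 61, …); the outermost shell
  is partially filled. The capacity sequence keeps the cumulative count
  inside radius `2k − 1` below the volume bound `(2k − 1)³`. `Rg` is
  computed from the shell radii about the **sphere center** (the
  construction's natural reference); the coordinate realization places
  each shell's monomers by the golden-angle (Fibonacci) spiral, which
  keeps same-shell neighbors ≥ 2 apart for the shell occupancies used.
- **Sparse sphere (SS).** The DS shell radii dilated by
  `(r_out + 2)/r_out`, i.e. the structure swollen by one extra diameter
  at the rim — a loosely packed globule.
- **Parabola (Pa).** Monomer centers on `y = x²` at **unit arc-length**
  steps, symmetric about the axis (even `N`: first pair at ±half-step;
  odd `N`: one monomer at the apex). The arc-length equation
  `A(x) = x·sqrt(1 + 4x²)/2 + asinh(2x)/4` is inverted with
  `scipy.optimize.brentq` (`xtol = 1e−14`). Unit steps (monomer
  *length*, not diameter) are what reproduces the reference value 3.5
  at `N = 20` and preserves the compactness ordering
  DS < Pa < SS < SR; diameter steps would double the size.
- **Self-avoiding walk (SAW).** Off-lattice: bonds of length 2 in
  uniformly random directions, a step is rejected if any non-bonded
  pair comes closer than 2; after 60 failed tries the chain restarts.
  Driven by `numpy.random.default_rng(seed)`, fully reproducible. The
  ensemble exponent fitted over `N ∈ {10, 20, 40, 80}` (2000 walks
  each) is ≈ 0.58, consistent with the 3-D SAW value 0.588.

## Chain models

Wormlike chain: `Rg² = l·Lp/3 − Lp² + 2Lp³/l − (2Lp⁴/l²)(1 − e^(−l/Lp))`
with contour length `l = N` effective monomer lengths and persistence
length `0 < Lp ≤ l`. Limits (tested): flexible coil
`Rg → sqrt(l/3)` for `l ≫ Lp`; rigid rod
`Rg/l → sqrt(4/3 − 2(1 − 1/e)) ≈ 0.263` at `Lp = l`. Freely jointed
chain: `Re-e = A0·sqrt(6N)`, hence `alpha = Rg/Re-e = 1/sqrt(6)`.

## Measures and regimes

`Rh = sqrt(5·Rg/3)` (default `"sqrt"` convention; `"linear"` gives
`Rh = 0.6·Rg`), `Re-e = 3.1·Rh`. A compact sphere of `N` unit monomers
has radius `R = N^(1/3)`, `Re-e = 2R`, and `Re-e/Rg = 2·sqrt(5/6) ≈ 1.8`.
`classify_regime` assigns the nearest anchor — by `nu`
(sphere 1/3, theta 0.5, SAW 0.588, good 0.6, rope 1.0) or by `alpha`
(rope `1/sqrt(12)`, theta `1/sqrt(6)`, sphere `1/1.8`) — with midpoint
boundaries; exact ties resolve toward the stiffer regime.

## Table regeneration and fixtures

`report.build_table(i)` recomputes each of the five reference tables
from the modules above; `build_fixture(i)` pairs every printed cell
(transcribed verbatim, as strings, in `_tables.py`) with its
recomputation and classifies it:

- `verified` — agrees within `max(base_tol, half a unit of the cell's
  printed last digit)`, base tolerance 0.005 for the 3-decimal salt
  table and 0.05 elsewhere;
- `typo-suspect` — a hand-curated list of eleven cells whose printed
  value contradicts the table's own generating formula by far more than
  rounding (e.g. a value that breaks its row's monotonicity);
- `reference-drift` — the remainder: consistent with chained rounded
  intermediates or slightly different inputs (e.g. the wormlike cells
  that sit 0.1–0.15 off the closed form).

Only `verified` cells are asserted; the other two classes are always
reported, and the tests pin the *exact* membership of the non-verified
sets so any classification change is loud. Known non-verified cells
include: three salt-table cells (`A0` at 225 mM and 20 M, `nu` at
525 mM), four wormlike cells (`(20, N/2)`, `(30, N)`, `(50, N/2)`,
`(60, N)`), the dense-sphere column at `N ∈ {50, 60}` (shell
accounting gives 4.82 and 5.03 against printed 4.9 and 5.3), the
sparse-sphere and chained `Re-e` cells at `N = 60`, and the printed
Pa/SS ordering inversion at `N = 50` (Pa 6.7 > SS 6.6).

Regeneration is fully deterministic: fixed row/column ordering, fixed
`%.6f` CSV formatting, no randomness anywhere in tables 1–5.

## Limitations

- The scaling law is an interpolation over 1 mM–20 M salt for 20–60
  monomer chains; nothing here extrapolates to long polymers.
- Crowding enters only through the caller-supplied deformation factor
  `F` or the potential-derived `1/beta`; no explicit crowder model.
- The configuration generators are idealized geometric references, not
  energy-minimized structures; the SAW is athermal (no attraction).
- The `Rh` and `Re-e` conversions are fixed empirical rules, not
  hydrodynamic calculations.
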