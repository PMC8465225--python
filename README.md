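# polyfluid

Size and shape of small polyelectrolytes — short single-stranded
nucleic-acid chains of 20–60 monomers — in salted, crowded biological
fluids, from closed-form models and small deterministic constructions.

The package puts five simple ingredients behind one API and one CLI:

1. **Salt-dependent scaling law** (`polyfluid.salt_scaling`) —
   `Rg = A0(s) · N^nu(s) · F(s, N, P)`, where the effective monomer length
   `A0` and the scaling exponent `nu` are affine in `log10` of the salt
   concentration `s` (in mM): `A0 = 11/4 + log10(s)/4` (Å) and
   `nu = 0.794 − 0.0674·log10(s)`. At zero crowding (`P = 0`) the
   deformation factor `F` is identically 1; for crowded fluids the caller
   supplies `F`, or uses the inverse compression factor `1/beta` derived
   from the effective potential. `nu` is clamped to `[1/3, 1]` (compact
   globule to rigid rope) with a warning outside the fitted salt range.
2. **Generalized Lennard-Jones effective potential**
   (`polyfluid.effective_potential`) —
   `V(r) = a·eps·[(sigma/r)^m − (sigma/r)^n]` with `m > n > 0`,
   `a = beta^m`, `b = beta^(m−n)` and equilibrium extent
   `r_m = beta·sigma`, `beta = (m/n)^(1/(m−n))`. The derivative splits
   into a short-range stretching force `F1 < 0` and a long-range entropic
   compressing force `F2 > 0` that cancel at `r_m`. A companion
   ellipsoid force-ratio relation `F1/F2 = 1 − 2d/sqrt(d² + c²)` gives
   −0.41 for a sphere (`c = d`) and −0.79 at `c = d/2`.
3. **Idealized configurations** (`polyfluid.configurations`) — explicit
   coordinate generators for a straight rope (SR), ring, dense sphere
   (DS, concentric shells of capacities 1, 7, 19, 37, 61, …), sparse
   sphere (SS, the same shells dilated by one monomer diameter), a
   parabola (Pa) traversed in unit arc-length steps, and an off-lattice
   self-avoiding walk (SAW), plus a coordinate-based radius-of-gyration
   calculator `rg_of` and XYZ export.
4. **Analytic chain models** (`polyfluid.chain_models`) — the
   wormlike-chain `Rg(l, Lp)` interpolating between the flexible coil
   (`sqrt(l/3)`) and rigid rod (`≈ l/4`) limits, and the freely jointed
   chain `Re-e = A0·sqrt(6N)`.
5. **Measure conversions and regime classification**
   (`polyfluid.measures`) — `Rh = sqrt(5·Rg/3)`, `Re-e = 3.1·Rh`, the
   compact-sphere ratio `Re-e/Rg = 2·sqrt(5/6) ≈ 1.8`, and a classifier
   mapping `nu` (or `alpha = Rg/Re-e`) to the nearest regime among
   sphere / theta / SAW / good solvent / rope.

A sixth module, `polyfluid.report`, regenerates the five reference
tables these models were calibrated against and compares every cell with
a transcribed fixture (see *Fidelity and known discrepancies* below).

## Worked example

Radius of gyration of a 40-mer at physiological-like salt (125 mM),
with the chained hydrodynamic and end-to-end measures for a 20-mer at
low salt:

```
$ polyfluid scaling --salt 125 --n 40
{"salt_mM": 125.0, "N": 40, "P": 0.0, "A0": 1.0, "nu": 0.652668265123257, "Rg": 11.107433330068742}

$ polyfluid measures --salt 12.5 --n 20
{"salt_mM": 12.5, "N": 20, "Rg": 8.646302224018845, "Rh": 3.796116924792764, "Ree": 11.76796246685757, "alpha": 0.734732308024406, "convention": "sqrt", "regime": "good"}
```

The same numbers from Python, together with the potential's equilibrium
point and two of the explicit configurations:

```python
>>> from polyfluid import (SaltConditions, ScalingQuery, rg_scaling,
...                        PotentialParams, dense_sphere, rg_of, wormlike_rg)
>>> rg_scaling(SaltConditions(125.0), ScalingQuery(40))
11.107433330068742
>>> p = PotentialParams()          # classic (m, n) = (12, 6)
>>> p.r_m, p.a, p.b                # equilibrium extent and prefactors
(1.122462048309373, 4.000000000000002, 2.0000000000000004)
>>> rg_of(dense_sphere(40))        # 40 monomers in concentric shells
4.471983983719386
>>> wormlike_rg(l=20.0, Lp=1.0)    # flexible 20-mer
2.400347197110654
```

Other CLI verbs: `polyfluid potential` (CSV curve or `--rm` JSON),
`polyfluid config --shape ds --n 40 --xyz out.xyz`, `polyfluid rg`,
`polyfluid table --id 3 --out t3.csv`, and `polyfluid verify`.

## Fidelity and known discrepancies

The reference tables were transcribed verbatim into
`polyfluid._tables`, and every printed cell is recomputed from the
model modules and classified as `verified` (reproduces within the
printed precision), `typo-suspect` (contradicts the table's own
generating formula by far more than rounding — e.g. a printed 3.38
where the formula gives 3.338), or `reference-drift` (consistent with
chaining rounded intermediates or slightly different inputs). Only
verified cells are asserted by the tests; the other two classes are
reported by `polyfluid verify` so the disagreements stay visible. The
exact discrepancy sets are themselves asserted, so a change in any
cell's classification fails the suite. See `docs/methods.md` for the
full model description and the reasoning behind each convention.
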