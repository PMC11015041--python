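# Methods

## Scope and model structure

`psmasim` simulates the delivery of a PSMA-targeted radioligand
(¹⁷⁷Lu-PSMA-617) into a solid tumor embedded in normal tissue, on a voxel
phantom. The model has four coupled layers:

1. **Steady interstitial fluid flow** (Darcy + Starling), solved once per
   phantom. Physiological and geometric parameters are time-independent:
   the simulated 50 h horizon is far shorter than the time scale of tumor
   growth, and angiogenesis, vessel geometry and moving boundaries are out
   of scope.
2. **Plasma pharmacokinetics**: a fitted one-compartment clearance
   (`α = 0.0521 h⁻¹`) driving both bolus and constant-rate-infusion input.
3. **Ligand transport**: six convection-diffusion-reaction fields (hot/cold
   × free/bound/internalized) with Patlak transvascular exchange and
   lymphatic drainage in normal tissue only.
4. **Receptor trafficking**: four per-voxel ODE pools (free/occupied ×
   surface/endosome) supplying the free-receptor field `F_s` that the
   binding terms of the transport layer consume.

Radioactive decay is applied in tissue only: each hot species loses
`λ C_hot` and the corresponding cold species gains it, so hot+cold sums are
decay-free by construction. The plasma clearance `α` is used as fitted and
decay is *not* additionally applied inside `C_p`; hot and cold ligand share
the same `α` (the model gives no reason to distinguish them).

## Units

Canonical internal units are cm, s, Pa, and nmol per litre. All tabulated
constants (conventionally quoted in mmHg, minutes, hours) are converted once
at load time; `ParameterSet.UNITS` documents the canonical unit of every
field and `psmasim.params.CONFIG_UNITS` the conventional unit expected from
configuration files. 1 mmHg = 133.322 Pa.

## Key parameters

| symbol | default | unit | meaning |
|---|---|---|---|
| `D_eff` | 8.7e-7 | cm²/s | free-ligand diffusion (uniform; per-tissue override available) |
| `D_R` | 50 / 500 / 200 | nmol/L | tumor receptor density (scenarios tumor1/2/3); normal tissue = 0.1× |
| `k_on`, `k_off` | 0.046, 0.046 | L/(nmol·min), 1/min | association / dissociation |
| `k_int` | 0.001 | 1/min | internalization of occupied receptors |
| `k_ec` | 0.007 | 1/min | constitutive endocytosis of free receptors |
| `k_rec` | 0.15 | 1/min | endosomal recycling (sweeps cover 1e-4..1e-1) |
| `k_deg` | 2.9891e-4 | 1/s | lysosomal degradation; sorting fractions f₁ = f₂ = 0.5 |
| `k_syn` | 0.0118 | 1/min | occupancy-driven receptor synthesis |
| `k_rel` | 2e-4 | 1/min | release of internalized ligand (pure outflow, see below) |
| `λ` | 7.15e-5 | 1/min | ¹⁷⁷Lu decay (half-life 6.73 d) |
| `P` | 3.3e-4 | cm/s | vessel wall solute permeability |
| `σ_f` | 0.9 | – | filtration reflection coefficient |
| `FV_i`, `FV_c` | 0.39, 0.61 | – | interstitial / cellular volume fractions |
| `V` (plasma) | 3.0 | L | plasma volume; not fixed by the model source, set to a typical adult value and configurable — only `C_p = A/V` matters downstream, and all sweep conclusions are ratios insensitive to it |

Flow constants (hydraulic conductivities, vascular/osmotic pressures,
reflection coefficients, `S/V`) are per-tissue; tumor tissue has no
lymphatic term. The tumor Starling equilibrium pressure is
`p_e = p_B − σ_s(π_B − π_i)` = 11.5 mmHg = 1533.2 Pa, which sets the scale
of the elevated tumor interstitial pressure.

Decisions taken where the formulation was ambiguous:

* `V_r = 1.2e-22 mol m⁻³ s⁻¹` is kept as printed even though it is
  numerically negligible on the nmol/L scale (its magnitude suggests a
  per-cell count convention in the trafficking literature it descends
  from); it is configurable.
* The normalization volume in the trans-capillary Peclet number is read as
  the tissue volume of the `P·S/V` product, i.e. `Pe = φ_B(1−σ_f)/(P·S/V)`,
  consistent with the exchange source term.
* `k_rel` removes internalized ligand from the system (no destination
  compartment is defined for it).
* Receptor pools start with all receptors free on the surface at the tissue
  density; ligand fields start at zero.
* The bound-ligand fields (`C_B`, `C_BU`) and the occupied-receptor pools
  (`RP_s`, `RP_e`) are parallel ledgers of the same binding events with
  different loss structures; they are evolved independently as formulated
  (the transport binding terms consume `F_s`), and the simulator records
  `max_t |RP_s − (C_B + C_BU)|` as a diagnostic of their divergence rather
  than forcing agreement.

## Discretization and numerics

**Flow.** Cell-centered finite volumes on the voxel grid; face
transmissibilities use harmonic averaging of `K`, which enforces normal-flux
continuity at the tumor-normal interface without explicit interface
equations. The outer Dirichlet `p=0` acts on the box faces at half-cell
distance. Both Starling terms are linear in `p`, so the system
`(A + diag(bV)) p = aV` is SPD and solved directly (small grids) or by
Jacobi-preconditioned CG to a 1e-10 relative residual. Verified properties:
discrete divergence identity `div v = φ_B − φ_L` to machine precision,
global fluid balance against boundary outflow, a discrete maximum principle,
agreement with a high-resolution 1-D radial two-region oracle at the sphere
center, and ~2nd-order convergence on a manufactured cosine solution.

**Transport.** Diffusion by central differences (harmonic face averaging),
advection of `R_f v` by first-order upwind. Interstitial transport here is
strongly diffusion-dominated (tissue-scale Peclet ≪ 1), so upwind numerical
diffusion is immaterial. Outer boundary: zero diffusive flux; advective
outflow where the Darcy velocity points outward; advective inflow carries
zero outside concentration. Bound and internalized fields are immobile.

**Time stepping.** Lie splitting per step (default `dt = 0.1 min`, 50 h
horizon): (1) explicit advection-diffusion of the free fields,
automatically sub-stepped if the explicit stability limit requires it (it
does not on the default grids); (2) a linearly implicit (backward-Euler)
update of the reaction/exchange network in which the stiff free-bound 2×2
blocks (hot, then cold with the decay source, then the surface-receptor
pair) are solved in closed form per voxel, with the receptor field lagged
one step — a segregated treatment. The scheme is unconditionally stable for
the reaction part, positivity-preserving up to the explicit transport
tendency (negative values below −1e-9 nmol/L are counted and clipped;
counts are reported on the result). Halving the step changes tumor TIA by
< 0.01% in practice (the acceptance suite enforces < 0.5%), and the engine
agrees with an independent LSODA integration of the 0-D kinetics at
rtol 1e-11 to ~0.01% on tumor-averaged fields.

**Batching.** Members of a sweep (different protocols, `k_rec`, receptor
densities) share the phantom, flow solve and operators and are advanced
together, vectorized over a leading batch axis.

**TIA.** Labeled amount in a region is
`V_vox Σ [FV_i(C_F + C_B) + FV_c C_I]`; activity converts nmol to molecules
times `λ`; TIA integrates activity over the horizon by the trapezoid rule on
the 5-min output grid. Absolute TIA scales with tumor volume, so only
ratios, orderings and argmax locations are meaningful across geometries.

## Phantoms

Synthetic phantoms stand in for patient imaging: label 0 = outside the
computational domain, 1 = normal tissue, 2 = tumor; voxel-center coordinate
convention (position = origin + index × spacing, cm). Generators produce a
centered sphere or a lobed ellipsoid (seeded smooth quadrupole-like surface
modulation, regenerated if the perturbation disconnects the tumor); a
resolution guard keeps ≥ ~10 voxels across the tumor. Masks round-trip
through NIfTI-2 (spacing stored in mm, the format's native unit; the NIfTI-2
header keeps the affine in double precision). Field snapshots export as
NIfTI float volumes, time series as CSV.

Default problem sizes, chosen so a full coupled run takes about a minute on
one core: sweeps run on a 0.5 cm spherical tumor centered in a 2 cm
normal-tissue cube at 0.1 cm spacing (21³ voxels); the interstitial-pressure
validation solve uses a 3 cm cube at 0.05 cm spacing (61³). The pressure
plateau in the tumor core is grid-insensitive (< 3% change on refinement)
because the Starling screening length (~0.03 cm) is small against the tumor
radius.

What the phantoms do *not* emulate: real tumors are lobed, spatially
heterogeneous in vascularity and receptor expression, and embedded in
anatomically constrained normal tissue. Passing tests on spherical
surrogates therefore support the *mechanistic* claims (orderings, ratios,
argmax locations, scale estimates) but not absolute patient-level TIA
values, which additionally require the true tumor volume and geometry.

## Characteristic scales

The near-vessel penetration length of free ligand is
`L_F = 2D/(√(v² + 4 K_F D) − v)` with capture rate `K_F = D_R k_on`
(`≈ 0.038 s⁻¹` at 50 nmol/L), giving `L_F ≈ 4.8e-3 cm` at `v = 1e-6 cm/s`
and a diffusion time `T_d = L_F²/D = 1/K_F ≈ 26 s` at `v = 0`. The
advection time follows as `T_a = T_d/Pe`. For the trans-capillary Peclet
number the report evaluates both the full Starling driving term
`L_p(ΔP − σ_sΔπ)(1−σ_f)/P ≈ 2e-5` and the bare pressure-difference form
`L_p ΔP/P ≈ 3.7e-3` for the averaged pressures (2079.8 Pa vascular, 1500 Pa
interstitial); the pressure-difference variant is the one matching the
order-1e-3 value conventionally quoted for these parameters, and is flagged
as the headline. Either way the conclusion is the same: transvascular
exchange is diffusion-dominated.

## Known limitations and a documented discrepancy

* **Occupancy-driven receptor synthesis dominates the trafficking
  dynamics.** With the constants above, the synthesis term `k_syn RP_s`
  (0.0118 min⁻¹ per occupied receptor) exceeds every receptor loss pathway
  (the occupied internalize-and-degrade path loses ~1e-4 min⁻¹, the free
  endocytose-and-degrade path ~7.5e-4 min⁻¹). Under a 100 nmol dose, tissue
  free ligand tracks plasma within seconds (exchange rate `P·S/V ≈ 4 min⁻¹`)
  and surface occupancy stays near 1 for most of the 50 h, so the receptor
  pool *grows* at ~0.01 min⁻¹ instead of depleting. Two consequences,
  confirmed both by the 3-D solver and by an independent 0-D LSODA oracle
  (which agree with each other to 0.01%): the recycling rate changes tumor
  TIA only weakly (fold ≈ 1.1 between `k_rec` = 1e-4 and 1e-1 min⁻¹ at
  density 50 nmol/L, ≈ 1.07 at 500 — the ordering, faster recycling →
  higher TIA, and its saturation with density are robust), and tumor TIA is
  monotone increasing in the injected amount over 100-1000 nmol (capture is
  supply-limited, so there is no interior optimum). Reports of a ~3-fold
  recycling effect and an 800 nmol optimum for this class of model are not
  reproduced by these equations with these constants; producing an interior
  amount-optimum would require occupied receptors to be degraded *faster*
  than free ones (`k_int > k_ec`), the opposite of the tabulated rates. The
  equations are implemented as formulated; the acceptance suite keeps the
  corresponding checks at their published expectations and they fail
  honestly.
* The ligand and receptor ledgers are not mutually conservative (see
  above); the divergence diagnostic is typically of the order of the bound
  concentration itself over 50 h.
* Uniform vascular parameters per tissue class: no microvessel geometry,
  no perfusion heterogeneity, no vascular compliance.
* No dosimetry: TIA is the end point; absorbed dose, β-particle transport
  and cell survival are out of scope, as are organ-at-risk kinetics.
* Receptor model ignores fast surface processes (dimerization, activation)
  and spatial receptor heterogeneity beyond the tumor/normal split.
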