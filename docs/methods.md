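# Methods

## Constitutive model

The wall material is incompressible (J = det F = 1, enforced through a
Lagrange pressure p) and hyperelastic, with the orthotropic
Holzapfel–Ogden baseline energy written in the invariants I₁, I₄f, I₄s,
I₄fs of the right Cauchy–Green tensor C and the material triad
(f₀, s₀, n₀). Myocytes and collagen fibres are assumed to buckle in
compression, so the I₄f and I₄s exponentials contribute only where
I₄ᵢ > 1; the (I₄ᵢ − 1) prefactor structure makes both the energy and the
stress continuous (C¹) across the switch. The switch is never applied to
the I₄fs term or to the residual-stress terms. The isotropic prefactor
is a·exp[b(I₁ − 3)] in every formulation. I₂ is computed for
completeness but appears in no energy; it is informational only.

Residual stress is a symmetric Cauchy stress τ living in the unloaded
configuration B_r, which is distinct from the fictitious stress-free
configuration B₀. It enters the energy through the coupling invariants
I₆ = tr(τC), I₇ = tr(τC²) (and, in a disabled-by-default research mode,
the quadratic invariants I₈ = tr(τ²C), I₉ = tr(τ²C²)). Two closed
formulations are provided:

* simple: W += ½I₆, stress term Σ = FτFᵀ. Appropriate when B ≈ I so
  that ΣB ≈ Σ.
* extended: W += ¼I₆ + ⅛I₇, stress term ½Σ + ¼(ΣB + BΣ).

Both satisfy the unloaded-configuration consistency conditions
2W₁ = p⁽ʳ⁾ = a, 2(W₆ + 2W₇) = 1, W₈ + 2W₉ = 0, so that σ(F=I, p=a) = τ
identically — this is verified exactly in the tests, and is the reason
neither formulation introduces new material parameters. The difference
between the two stresses is −¼[Σ(B−I) + (B−I)Σ], exactly linear in τ
and vanishing linearly in ‖B − I‖, which is why they agree closely for
physiological (sub-kPa) residual stress at diastolic strains. The
quadratic I₈/I₉ terms are omitted from both defaults on the small-τ
argument; the research-mode entry point accepts user-supplied constant
W₆…W₉ but enforces the consistency conditions.

When τ is diagonal in the fibre frame (the measured-strain data support
this), I₆ and I₇ reduce to combinations of the structural invariants:
I₆ = τ_nn I₁ + (τ_ff − τ_nn)I₄f + (τ_ss − τ_nn)I₄s and
I₇ = τ_ff I₅f + τ_ss I₅s + τ_nn I₅n, using I₁ = I₄f + I₄s + I₄n for an
orthonormal triad. These reductions are exposed and cross-checked
against the direct traces.

### Material parameters

Eight non-negative constants: stress-like moduli a, a_f, a_s, a_fs (kPa)
and dimensionless exponents b, b_f, b_s, b_fs. The packaged defaults
(a = 0.236, b = 10.81, a_f = 20.04, b_f = 14.15, a_s = 3.72, b_s = 5.16,
a_fs = 0.41, b_fs = 11.3) are an orthotropic fit to canine simple-shear
data that is standard in human-LV diastolic modelling. They are shipped
as configuration data (`data/material_default.yaml`), strict-parsed, and
overridable per run; nothing in the code depends on their specific
values.

### The Lagrange pressure

Incompressibility leaves p pointwise indeterminate; it is never a
material output. `cauchy_stress` returns σ̂ = F∂W/∂F and lets the caller
fix p, either directly or through a prescribed normal traction
(`solve_pressure`). In the tube solvers p is closed by the radial
equilibrium integration, which is the standard thick-walled-tube
treatment.

## Residual stress estimation

### From measured transmural strains

Input is a table of Euler–Almansi strain components e₀(ξ) in the fibre
frame at wall-depth fractions ξ ∈ [0, 1] (0 = endocardium). The
pre-deformation satisfies B⁽ʳ⁾ = (I − 2e₀)⁻¹, which exists iff I − 2e₀
is positive definite; inadmissible stations are reported by ξ. The
default estimator uses only the ground-matrix energy,
τ = a exp[b(I₁⁽ʳ⁾ − 3)]B⁽ʳ⁾ − aI, encoding the assumption that fibres
are wavy and hence relaxed in the unloaded state. The opt-in orthotropic
variant instead evaluates the full energy at F₀ = (B⁽ʳ⁾)^{1/2} (the
symmetric, rotation-free root) with the tension switch active, and
reduces exactly to the isotropic estimate when no anisotropic term is
engaged. Both are exactly zero at zero strain, and equivariant under
simultaneous rotation of strain and frame.

The estimated field is pointwise and inherits the measurement's
incompatibility: it does not satisfy Div τ = 0. `divergence_diagnostic`
reports the discrete radial-equilibrium residual and never rejects a
field on it. Interpolation of a profile onto a solver grid is
componentwise monotone cubic (PCHIP), chosen to avoid overshoot between
stations; this is a package choice, as no canonical interpolation exists
for such data.

Fibre-frame shear strains are small in the measurements this emulates;
`drop_shears` zeroes them when every |shear| ≤ 0.02 and raises
otherwise, making the negligible-shear assumption explicit and
checkable rather than silent.

### The synthetic strain fixture

Measured bead-array strain tables are not redistributable, so the
package generates a synthetic profile with the same qualitative
structure: smooth low-order transmural variation, compressive fibre
strain at the endocardium (−0.04) grading to tensile at the epicardium
(+0.06), cross-fibre and normal components of the opposite trend with
slightly negative trace deviation at the endocardium, shears bounded by
0.005, all magnitudes ≤ 0.1. Endpoint values are exact by construction
(the seeded quadratic perturbation vanishes at the surfaces), so the
sign structure of the resulting τ_ff — compressive endo, tensile epi —
is a property of the generator's defaults, which are fixed and not
tuned per run. What the fixture does not emulate: measurement noise,
inter-animal variability, transmural asymmetry beyond a quadratic, or
strain incompatibility patterns of real tissue — so tests passing on
the fixture validate the estimator chain, not any physiological claim.

### Opening-angle method

The stress-free configuration is an opened sector R ∈ [R_i, R_o] with
opening angle α (interface in degrees, stored in radians) and axial
stretch λ_z; κ = 2π/(2π − α). The sector-to-tube map
r(R) = √((R² − R_i²)/(κλ_z) + r_i²) is isochoric by construction
(λ_r λ_θ λ_z = 1 identically). The constitutive response driving the
locked-in stress is by default the ground-matrix part of the energy —
consistent with the relaxed-fibre assumption of the strain-based
estimator — with the full orthotropic law as an option (fibre angles
then follow the same transmural rule as the inflation model).

The closed inner radius r_i is determined by a bracketed Brent solve
(bracket [0.2, 2]·R_i, xtol 1e−10 cm) on the requirement that the
integrated radial stress, started from τ_rr(r_i) = 0, also vanish at
r_o. Quadrature is composite Simpson on a fine grid (≥ 801 points; the
returned profile subsamples it), giving ~1e−10 kPa residual traction at
the free surface for the smooth isotropic response. In orthotropic mode
the tension switch introduces a kink in the integrand and the achieved
tolerance degrades to ~1e−5 kPa, still far below the 1e−3 kPa contract.
p(r) is closed from the radial integration; τ_θθ and τ_zz follow from
the constitutive response minus p.

Rotation into the fibre frame uses τ_ab = a·τ̄b for a, b ∈ (f₀,s₀,n₀).
With the default helical rule the fibre-frame shears are non-zero but
smaller than the normal components; they are zeroed by default
(`keep_shear=False`) to produce a principal-in-fibre-frame tensor, the
form the reduced invariants expect.

## The cylinder surrogate

The left ventricle is idealised as the same thick-walled tube the
opening-angle method closes; absolute stresses of an imaged,
thick-apexed ventricle are out of scope and not claimed. The fibre
angle varies linearly from +60° (endo) to −60° (epi) and the sheet
angle from −45° to +45°; the frame convention is
f₀ = cos φ e_θ + sin φ e_z, s₀ = e_r rotated about f₀ by β, n₀ = f₀×s₀.
The endo/epi sign assignment of the fibre angle is a convention switch
(`FibreRule`), since only the range is physically constrained.

Inflation at fixed λ_z is the axisymmetric isochoric map
r² = r_i,def² + (R² − R_i²)/λ_z. The deformed inner radius is found by
Brent root solve on the integrated radial equilibrium with
σ_rr = −P at the endocardium and 0 at the epicardium (P in mmHg at the
interface, 1 mmHg = 0.133322 kPa internally). The residual field τ(ξ)
is attached materially to the unloaded wall and pushed forward through
Σ = FτFᵀ. Transmural profiles report both cylindrical components and
normal stresses along the push-forward (normalised) fibre directions.
Solver defaults: 200-point reporting grid over a ≥ 801-point internal
grid, root tolerance 1e−10 cm. With a helical fibre rule the stress
field has θ–z shear components; as in the classical
extension–inflation treatment only the radial equilibrium equation is
enforced (no twist degree of freedom), which is exact for the
fibre-angle-symmetric rules used here and an approximation otherwise.

P–V curves use cavity volume per unit unloaded length, V = π r_i,def²
λ_z, normalised to [0, 1] over the pressure grid for shape comparison.
Model comparison (`compare_models`) scales per-component differences by
the profile maximum magnitude — a pointwise relative difference would
be dominated by zero crossings of σ_ss and σ_nn — with a 5% "almost
identical" flag.

## Inverse unloading

At cylinder scale the geometry is the radius pair (r_i, r_o), and the
backward-displacement update is x_{k+1} = x_m − (inflate(x_k, P) − x_k).
Convergence demands both max radius mismatch ≤ 1e−4 cm and relative
cavity-area mismatch ≤ 0.5% (50-iteration budget); divergence (mismatch
exceeding 5× its initial value) raises with the history attached. The
residual field is re-attached to each new unloaded estimate through its
depth parameterisation by default — mirroring the regeneration of fibre
structure per iterate in mesh-based practice — with a `freeze_tau` flag
to hold the first field fixed; for a purely depth-parameterised field
the two coincide, and a test pins that equivalence. Whether residual
stress should be present during unloading iterations at all is left to
the caller (pass a builder or not), as both positions appear in
practice.

## Numerical choices and degenerate inputs

* Incompressibility and symmetry checks: 1e−8 relative; J ≠ 1 states are
  flagged, not rejected, because measured strain data are not exactly
  isochoric.
* α = 0 short-circuits the opening-angle solve to the exact zero field.
* Zero-pressure inflation of a self-equilibrated residual field
  reproduces the identity deformation to the root tolerance; this is a
  consistency test of the whole chain (the residual field satisfies the
  same ODE the inflation shoots on).
* The stress implementation is verified against central finite
  differences of the energy (h = 1e−6) on random isochoric states; the
  oracle is an independent code path sharing only the energy.
* Finite-difference equilibrium diagnostics on reporting grids carry
  O(h²) discretisation error (~1e−3 kPa/cm at 201 points); genuine
  solver error is assessed against adaptive quadrature instead.

## Problem sizes

Default grids (201-point sector solve, 200-point inflation profiles,
9-point pressure grids) resolve all reported quantities to well beyond
reporting precision — halving the grids changes headline numbers in the
sixth digit — and keep any single solve below a second on one core.

## Known limitations

* The surrogate is a tube: no apex, no base constraint, no longitudinal
  curvature, and hence no claim on absolute stress magnitudes of an
  anatomical ventricle.
* Diastole only: no active tension, no viscoelasticity, no growth or
  remodelling.
* The opening-angle route assumes a single radial cut releases all
  residual stress; measured strain data suggest it underestimates the
  field, so the two estimators should be expected to differ
  quantitatively while agreeing in sign structure.
* Residual-stress invariants coupling τ with the fibre directions are
  not modelled (the τ–C coupling is assumed sufficient for small τ).
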