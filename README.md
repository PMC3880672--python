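# resmyo

Residual stress in passive ventricular myocardium, at desk scale.

Even with every external load removed, the ventricular wall is not
stress-free: a radially cut ring of myocardium springs open, and bead
displacement experiments measure non-zero transmural strain in the
unloaded heart. `resmyo` implements a modified Holzapfel–Ogden
constitutive law in which this residual stress enters the strain energy
through invariants that couple it to the deformation, two independent
ways of estimating the residual stress tensor, and a thick-walled
cylinder surrogate of the left ventricle for studying what residual
stress does to transmural stress distributions and pressure–volume
behaviour in diastole. It is written for cardiac-mechanics researchers
who want the constitutive and estimation machinery without a finite
element model attached.

## The model

The passive myocardium is a non-homogeneous, incompressible,
hyperelastic solid with an orthotropic microstructure described by the
local fibre / sheet / sheet-normal triad (f₀, s₀, n₀). The baseline
strain energy is the eight-parameter Holzapfel–Ogden law

    W = a/(2b) exp[b(I₁ − 3)]
      + Σ_{i=f,s} a_i/(2b_i) {exp[b_i(I₄ᵢ − 1)²] − 1}
      + a_fs/(2b_fs) {exp[b_fs I₄fs²] − 1},

with I₁ = tr C, I₄f = f₀·Cf₀, I₄s = s₀·Cs₀, I₄fs = f₀·Cs₀, and the
fibre/sheet terms active only in tension (I₄ᵢ > 1). A symmetric residual
Cauchy stress τ in the unloaded configuration is admitted through the
additional invariants I₆ = tr(τC) and I₇ = tr(τC²):

* **simple** formulation: W += ½ I₆, giving a stress contribution
  Σ = FτFᵀ;
* **extended** formulation: W += ¼ I₆ + ⅛ I₇, giving
  ½Σ + ¼(ΣB + BΣ).

No new material parameter is introduced: the coefficients are pinned by
requiring that in the unloaded state (F = I, p = a) the Cauchy stress
reduce exactly to τ, which forces 2W₁ = p⁽ʳ⁾ = a, 2(W₆ + 2W₇) = 1 and
W₈ + 2W₉ = 0.

τ itself is estimated two ways:

1. **from measured residual strains** — transmural Euler–Almansi strain
   profiles e₀ give B⁽ʳ⁾ = (I − 2e₀)⁻¹ and
   τ = a exp[b(I₁⁽ʳ⁾ − 3)] B⁽ʳ⁾ − aI (fibres assumed relaxed in the
   unloaded state; a full-orthotropic variant is available), and
2. **by the opening-angle method** — an opened stress-free sector of
   angle α is closed into a tube, and the locked-in stress follows from
   integrating dτ_rr/dr + (τ_rr − τ_θθ)/r = 0 with τ_rr = 0 on both wall
   surfaces.

The cylinder surrogate then inflates the residually stressed tube
through diastolic pressures (0–8 mmHg) with a helical fibre rule
(+60° → −60° endo→epi), and a backward-displacement iteration recovers
the unloaded radii from a loaded, "imaged" geometry.

## Worked example

Residual stress of the reference tube (α = 85°, sector radii
2.5–4.2 cm), then its effect on the fibre stress at 3 mmHg:

```python
import resmyo as rm

params = rm.MaterialParams.default()
sector = rm.CylinderGeometry.from_degrees(R_i=2.5, R_o=4.2, alpha_deg=85)
prof = rm.solve_residual_field(sector, params)
print(prof.r_i, prof.r_o)            # 1.7457 3.4276  (closed-tube radii, cm)
print(prof.tau_thth[0], prof.tau_thth[-1])   # -0.1209 0.0756 (kPa)

tube = rm.TubeGeometry(r_i=prof.r_i, r_o=prof.r_o)
field = rm.TauField.from_opening_angle(prof)
base = rm.inflate(tube, params, "baseline", None, P_mmHg=3.0)
with_tau = rm.inflate(tube, params, "simple", field, P_mmHg=3.0)
print(base.sigma_ff[0], with_tau.sigma_ff[0])    # 0.1494 0.0681 (endo, kPa)
print(base.sigma_ff[-1], with_tau.sigma_ff[-1])  # 0.1408 0.1867 (epi, kPa)
```

The closed tube carries compressive circumferential stress at the inner
wall (−0.12 kPa) and tensile at the outer wall (+0.08 kPa) — the classic
opened-ring signature. Under a 3 mmHg endocardial load, including the
residual stress lowers the endocardial fibre stress (0.149 → 0.068 kPa)
and raises the epicardial one (0.141 → 0.187 kPa), i.e. it evens out the
transmural distribution. The same computations are available from the
shell:

```sh
resmyo opening-angle --alpha-deg 85 --out tau.csv
resmyo inflate --model simple --tau-source opening_angle \
       --pressure-mmhg 3 --pressure-mmhg 8 --out-dir profiles/
resmyo unload --pi-mmhg 8 --ri-cm 1.83 --ro-cm 3.47 --model simple \
       --tau-source opening_angle
resmyo selftest
```

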