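# Default Holzapfel-Ogden parameters for passive ventricular myocardium:
# an orthotropic fit to canine simple-shear data.  Moduli (a, a_f, a_s,
# a_fs) in kPa; exponents (b, b_f, b_s, b_fs) dimensionless.
a: 0.236
b: 10.81
a_f: 20.04
b_f: 14.15
a_s: 3.72
b_s: 5.16
a_fs: 0.41
b_fs: 11.3
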