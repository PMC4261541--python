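# Generic per-element Lennard-Jones parameters (rmin/2 in Angstrom, epsilon in
# kcal/mol); combined by Lorentz-Berthelot rules.
element	rmin_half	epsilon
C	2.00	0.12
N	1.85	0.17
O	1.70	0.20
S	2.00	0.30
P	2.10	0.20
F	1.60	0.10
CL	1.95	0.25
BR	2.10	0.30
I	2.25	0.35
H	0.80	0.03
*	1.80	0.10
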