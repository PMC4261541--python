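# SYNTHETIC formal-charge set for protein atoms (elementary charges).
# Charged side-chain groups only; all other protein atoms are neutral.
# Antigen charges always come from the Mol2 input, never from this table.
residue	atom	charge
ASP	OD1	-0.50
ASP	OD2	-0.50
GLU	OE1	-0.50
GLU	OE2	-0.50
LYS	NZ	1.00
ARG	NE	0.20
ARG	NH1	0.40
ARG	NH2	0.40
*	OXT	-0.50
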