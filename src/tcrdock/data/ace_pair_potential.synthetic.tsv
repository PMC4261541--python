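# SYNTHETIC stand-in for the ACE atomic-contact-energy pair table.
# Additive model e(i,j) = (c_i + c_j)/2 over chemistry-motivated class propensities;
# deterministic, not fitted to crystal-structure statistics.
class_i	class_j	energy
N	N	0.2500
N	CA	-0.0250
N	C	0.0750
N	O	0.2750
N	GC	0.0000
N	CB	-0.3250
N	KNZ	0.6000
N	KCD	-0.1500
N	DOD	0.5500
N	RNH	0.4500
N	NND	0.3500
N	RNE	0.3250
N	SOG	0.3750
N	HNE	0.3250
N	YCZ	-0.2250
N	FCZ	-0.4750
N	LCD	-0.6000
N	CSG	-0.5250
CA	CA	-0.3000
CA	C	-0.2000
CA	O	0.0000
CA	GC	-0.2750
CA	CB	-0.6000
CA	KNZ	0.3250
CA	KCD	-0.4250
CA	DOD	0.2750
CA	RNH	0.1750
CA	NND	0.0750
CA	RNE	0.0500
CA	SOG	0.1000
CA	HNE	0.0500
CA	YCZ	-0.5000
CA	FCZ	-0.7500
CA	LCD	-0.8750
CA	CSG	-0.8000
C	C	-0.1000
C	O	0.1000
C	GC	-0.1750
C	CB	-0.5000
C	KNZ	0.4250
C	KCD	-0.3250
C	DOD	0.3750
C	RNH	0.2750
C	NND	0.1750
C	RNE	0.1500
C	SOG	0.2000
C	HNE	0.1500
C	YCZ	-0.4000
C	FCZ	-0.6500
C	LCD	-0.7750
C	CSG	-0.7000
O	O	0.3000
O	GC	0.0250
O	CB	-0.3000
O	KNZ	0.6250
O	KCD	-0.1250
O	DOD	0.5750
O	RNH	0.4750
O	NND	0.3750
O	RNE	0.3500
O	SOG	0.4000
O	HNE	0.3500
O	YCZ	-0.2000
O	FCZ	-0.4500
O	LCD	-0.5750
O	CSG	-0.5000
GC	GC	-0.2500
GC	CB	-0.5750
GC	KNZ	0.3500
GC	KCD	-0.4000
GC	DOD	0.3000
GC	RNH	0.2000
GC	NND	0.1000
GC	RNE	0.0750
GC	SOG	0.1250
GC	HNE	0.0750
GC	YCZ	-0.4750
GC	FCZ	-0.7250
GC	LCD	-0.8500
GC	CSG	-0.7750
CB	CB	-0.9000
CB	KNZ	0.0250
CB	KCD	-0.7250
CB	DOD	-0.0250
CB	RNH	-0.1250
CB	NND	-0.2250
CB	RNE	-0.2500
CB	SOG	-0.2000
CB	HNE	-0.2500
CB	YCZ	-0.8000
CB	FCZ	-1.0500
CB	LCD	-1.1750
CB	CSG	-1.1000
KNZ	KNZ	0.9500
KNZ	KCD	0.2000
KNZ	DOD	0.9000
KNZ	RNH	0.8000
KNZ	NND	0.7000
KNZ	RNE	0.6750
KNZ	SOG	0.7250
KNZ	HNE	0.6750
KNZ	YCZ	0.1250
KNZ	FCZ	-0.1250
KNZ	LCD	-0.2500
KNZ	CSG	-0.1750
KCD	KCD	-0.5500
KCD	DOD	0.1500
KCD	RNH	0.0500
KCD	NND	-0.0500
KCD	RNE	-0.0750
KCD	SOG	-0.0250
KCD	HNE	-0.0750
KCD	YCZ	-0.6250
KCD	FCZ	-0.8750
KCD	LCD	-1.0000
KCD	CSG	-0.9250
DOD	DOD	0.8500
DOD	RNH	0.7500
DOD	NND	0.6500
DOD	RNE	0.6250
DOD	SOG	0.6750
DOD	HNE	0.6250
DOD	YCZ	0.0750
DOD	FCZ	-0.1750
DOD	LCD	-0.3000
DOD	CSG	-0.2250
RNH	RNH	0.6500
RNH	NND	0.5500
RNH	RNE	0.5250
RNH	SOG	0.5750
RNH	HNE	0.5250
RNH	YCZ	-0.0250
RNH	FCZ	-0.2750
RNH	LCD	-0.4000
RNH	CSG	-0.3250
NND	NND	0.4500
NND	RNE	0.4250
NND	SOG	0.4750
NND	HNE	0.4250
NND	YCZ	-0.1250
NND	FCZ	-0.3750
NND	LCD	-0.5000
NND	CSG	-0.4250
RNE	RNE	0.4000
RNE	SOG	0.4500
RNE	HNE	0.4000
RNE	YCZ	-0.1500
RNE	FCZ	-0.4000
RNE	LCD	-0.5250
RNE	CSG	-0.4500
SOG	SOG	0.5000
SOG	HNE	0.4500
SOG	YCZ	-0.1000
SOG	FCZ	-0.3500
SOG	LCD	-0.4750
SOG	CSG	-0.4000
HNE	HNE	0.4000
HNE	YCZ	-0.1500
HNE	FCZ	-0.4000
HNE	LCD	-0.5250
HNE	CSG	-0.4500
YCZ	YCZ	-0.7000
YCZ	FCZ	-0.9500
YCZ	LCD	-1.0750
YCZ	CSG	-1.0000
FCZ	FCZ	-1.2000
FCZ	LCD	-1.3250
FCZ	CSG	-1.2500
LCD	LCD	-1.4500
LCD	CSG	-1.3750
CSG	CSG	-1.3000
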