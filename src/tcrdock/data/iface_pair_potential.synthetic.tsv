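# SYNTHETIC stand-in for the IFACE interface-recalibrated pair table.
# Derived from the ACE stand-in by compressing hydrophobic rewards and
# rewarding polar-polar interface contacts; deterministic, not statistics-fitted.
class_i	class_j	energy
N	N	0.0000
N	CA	-0.0150
N	C	0.0450
N	O	0.0150
N	GC	0.0000
N	CB	-0.1950
N	KNZ	0.2100
N	KCD	-0.0900
N	DOD	0.1800
N	RNH	0.1200
N	NND	0.0600
N	RNE	0.0450
N	SOG	0.0750
N	HNE	0.0450
N	YCZ	-0.1350
N	FCZ	-0.2850
N	LCD	-0.3600
N	CSG	-0.3150
CA	CA	-0.1800
CA	C	-0.1200
CA	O	0.0000
CA	GC	-0.1650
CA	CB	-0.3600
CA	KNZ	0.1950
CA	KCD	-0.2550
CA	DOD	0.1650
CA	RNH	0.1050
CA	NND	0.0450
CA	RNE	0.0300
CA	SOG	0.0600
CA	HNE	0.0300
CA	YCZ	-0.3000
CA	FCZ	-0.4500
CA	LCD	-0.5250
CA	CSG	-0.4800
C	C	-0.0600
C	O	0.0600
C	GC	-0.1050
C	CB	-0.3000
C	KNZ	0.2550
C	KCD	-0.1950
C	DOD	0.2250
C	RNH	0.1650
C	NND	0.1050
C	RNE	0.0900
C	SOG	0.1200
C	HNE	0.0900
C	YCZ	-0.2400
C	FCZ	-0.3900
C	LCD	-0.4650
C	CSG	-0.4200
O	O	0.0300
O	GC	0.0150
O	CB	-0.1800
O	KNZ	0.2250
O	KCD	-0.0750
O	DOD	0.1950
O	RNH	0.1350
O	NND	0.0750
O	RNE	0.0600
O	SOG	0.0900
O	HNE	0.0600
O	YCZ	-0.1200
O	FCZ	-0.2700
O	LCD	-0.3450
O	CSG	-0.3000
GC	GC	-0.1500
GC	CB	-0.3450
GC	KNZ	0.2100
GC	KCD	-0.2400
GC	DOD	0.1800
GC	RNH	0.1200
GC	NND	0.0600
GC	RNE	0.0450
GC	SOG	0.0750
GC	HNE	0.0450
GC	YCZ	-0.2850
GC	FCZ	-0.4350
GC	LCD	-0.5100
GC	CSG	-0.4650
CB	CB	-0.5400
CB	KNZ	0.0150
CB	KCD	-0.4350
CB	DOD	-0.0150
CB	RNH	-0.0750
CB	NND	-0.1350
CB	RNE	-0.1500
CB	SOG	-0.1200
CB	HNE	-0.1500
CB	YCZ	-0.4800
CB	FCZ	-0.6300
CB	LCD	-0.7050
CB	CSG	-0.6600
KNZ	KNZ	0.4200
KNZ	KCD	0.1200
KNZ	DOD	0.3900
KNZ	RNH	0.3300
KNZ	NND	0.2700
KNZ	RNE	0.2550
KNZ	SOG	0.2850
KNZ	HNE	0.2550
KNZ	YCZ	0.0750
KNZ	FCZ	-0.0750
KNZ	LCD	-0.1500
KNZ	CSG	-0.1050
KCD	KCD	-0.3300
KCD	DOD	0.0900
KCD	RNH	0.0300
KCD	NND	-0.0300
KCD	RNE	-0.0450
KCD	SOG	-0.0150
KCD	HNE	-0.0450
KCD	YCZ	-0.3750
KCD	FCZ	-0.5250
KCD	LCD	-0.6000
KCD	CSG	-0.5550
DOD	DOD	0.3600
DOD	RNH	0.3000
DOD	NND	0.2400
DOD	RNE	0.2250
DOD	SOG	0.2550
DOD	HNE	0.2250
DOD	YCZ	0.0450
DOD	FCZ	-0.1050
DOD	LCD	-0.1800
DOD	CSG	-0.1350
RNH	RNH	0.2400
RNH	NND	0.1800
RNH	RNE	0.1650
RNH	SOG	0.1950
RNH	HNE	0.1650
RNH	YCZ	-0.0150
RNH	FCZ	-0.1650
RNH	LCD	-0.2400
RNH	CSG	-0.1950
NND	NND	0.1200
NND	RNE	0.1050
NND	SOG	0.1350
NND	HNE	0.1050
NND	YCZ	-0.0750
NND	FCZ	-0.2250
NND	LCD	-0.3000
NND	CSG	-0.2550
RNE	RNE	0.0900
RNE	SOG	0.1200
RNE	HNE	0.0900
RNE	YCZ	-0.0900
RNE	FCZ	-0.2400
RNE	LCD	-0.3150
RNE	CSG	-0.2700
SOG	SOG	0.1500
SOG	HNE	0.1200
SOG	YCZ	-0.0600
SOG	FCZ	-0.2100
SOG	LCD	-0.2850
SOG	CSG	-0.2400
HNE	HNE	0.0900
HNE	YCZ	-0.0900
HNE	FCZ	-0.2400
HNE	LCD	-0.3150
HNE	CSG	-0.2700
YCZ	YCZ	-0.4200
YCZ	FCZ	-0.5700
YCZ	LCD	-0.6450
YCZ	CSG	-0.6000
FCZ	FCZ	-0.7200
FCZ	LCD	-0.7950
FCZ	CSG	-0.7500
LCD	LCD	-0.8700
LCD	CSG	-0.8250
CSG	CSG	-0.7800
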