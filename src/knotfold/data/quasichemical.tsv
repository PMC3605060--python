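	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	-0.5400	-0.6450	0.2550	0.2550	-0.6900	-0.2100	0.2100	-0.9450	0.3150	-0.8400	-0.5550	0.2550	-0.0300	0.2550	0.4050	-0.1500	-0.1650	-0.9000	-0.1350	-0.0750
C	-0.6450	-0.7500	0.1500	0.1500	-0.7950	-0.3150	0.1050	-1.0500	0.2100	-0.9450	-0.6600	0.1500	-0.1350	0.1500	0.3000	-0.2550	-0.2700	-1.0050	-0.2400	-0.1800
D	0.2550	0.1500	1.0500	1.0500	0.1050	0.5850	1.0050	-0.1500	1.1100	-0.0450	0.2400	1.0500	0.7650	1.0500	1.2000	0.6450	0.6300	-0.1050	0.6600	0.7200
E	0.2550	0.1500	1.0500	1.0500	0.1050	0.5850	1.0050	-0.1500	1.1100	-0.0450	0.2400	1.0500	0.7650	1.0500	1.2000	0.6450	0.6300	-0.1050	0.6600	0.7200
F	-0.6900	-0.7950	0.1050	0.1050	-0.8400	-0.3600	0.0600	-1.0950	0.1650	-0.9900	-0.7050	0.1050	-0.1800	0.1050	0.2550	-0.3000	-0.3150	-1.0500	-0.2850	-0.2250
G	-0.2100	-0.3150	0.5850	0.5850	-0.3600	0.1200	0.5400	-0.6150	0.6450	-0.5100	-0.2250	0.5850	0.3000	0.5850	0.7350	0.1800	0.1650	-0.5700	0.1950	0.2550
H	0.2100	0.1050	1.0050	1.0050	0.0600	0.5400	0.9600	-0.1950	1.0650	-0.0900	0.1950	1.0050	0.7200	1.0050	1.1550	0.6000	0.5850	-0.1500	0.6150	0.6750
I	-0.9450	-1.0500	-0.1500	-0.1500	-1.0950	-0.6150	-0.1950	-1.3500	-0.0900	-1.2450	-0.9600	-0.1500	-0.4350	-0.1500	-0.0000	-0.5550	-0.5700	-1.3050	-0.5400	-0.4800
K	0.3150	0.2100	1.1100	1.1100	0.1650	0.6450	1.0650	-0.0900	1.1700	0.0150	0.3000	1.1100	0.8250	1.1100	1.2600	0.7050	0.6900	-0.0450	0.7200	0.7800
L	-0.8400	-0.9450	-0.0450	-0.0450	-0.9900	-0.5100	-0.0900	-1.2450	0.0150	-1.1400	-0.8550	-0.0450	-0.3300	-0.0450	0.1050	-0.4500	-0.4650	-1.2000	-0.4350	-0.3750
M	-0.5550	-0.6600	0.2400	0.2400	-0.7050	-0.2250	0.1950	-0.9600	0.3000	-0.8550	-0.5700	0.2400	-0.0450	0.2400	0.3900	-0.1650	-0.1800	-0.9150	-0.1500	-0.0900
N	0.2550	0.1500	1.0500	1.0500	0.1050	0.5850	1.0050	-0.1500	1.1100	-0.0450	0.2400	1.0500	0.7650	1.0500	1.2000	0.6450	0.6300	-0.1050	0.6600	0.7200
P	-0.0300	-0.1350	0.7650	0.7650	-0.1800	0.3000	0.7200	-0.4350	0.8250	-0.3300	-0.0450	0.7650	0.4800	0.7650	0.9150	0.3600	0.3450	-0.3900	0.3750	0.4350
Q	0.2550	0.1500	1.0500	1.0500	0.1050	0.5850	1.0050	-0.1500	1.1100	-0.0450	0.2400	1.0500	0.7650	1.0500	1.2000	0.6450	0.6300	-0.1050	0.6600	0.7200
R	0.4050	0.3000	1.2000	1.2000	0.2550	0.7350	1.1550	-0.0000	1.2600	0.1050	0.3900	1.2000	0.9150	1.2000	1.3500	0.7950	0.7800	0.0450	0.8100	0.8700
S	-0.1500	-0.2550	0.6450	0.6450	-0.3000	0.1800	0.6000	-0.5550	0.7050	-0.4500	-0.1650	0.6450	0.3600	0.6450	0.7950	0.2400	0.2250	-0.5100	0.2550	0.3150
T	-0.1650	-0.2700	0.6300	0.6300	-0.3150	0.1650	0.5850	-0.5700	0.6900	-0.4650	-0.1800	0.6300	0.3450	0.6300	0.7800	0.2250	0.2100	-0.5250	0.2400	0.3000
V	-0.9000	-1.0050	-0.1050	-0.1050	-1.0500	-0.5700	-0.1500	-1.3050	-0.0450	-1.2000	-0.9150	-0.1050	-0.3900	-0.1050	0.0450	-0.5100	-0.5250	-1.2600	-0.4950	-0.4350
W	-0.1350	-0.2400	0.6600	0.6600	-0.2850	0.1950	0.6150	-0.5400	0.7200	-0.4350	-0.1500	0.6600	0.3750	0.6600	0.8100	0.2550	0.2400	-0.4950	0.2700	0.3300
Y	-0.0750	-0.1800	0.7200	0.7200	-0.2250	0.2550	0.6750	-0.4800	0.7800	-0.3750	-0.0900	0.7200	0.4350	0.7200	0.8700	0.3150	0.3000	-0.4350	0.3300	0.3900
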