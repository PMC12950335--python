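# Wine-like test mixture for ufcosy.
# Shifts for TSP (0.00 ppm) and tartrate (4.47 ppm) anchor two-point
# calibration; all other metabolite shifts/couplings/concentrations are
# illustrative literature-style values, NOT measured ones.
system	site	shift_ppm	n_protons	J_partner	J_hz	concentration	class	T2_s
water	H	4.79	2			50000.0	solvent	0.3
ethanol	CH3	1.18	3	CH2	7.0	3300.0	solvent	0.6
ethanol	CH2	3.65	2	CH3	7.0	3300.0	solvent	0.6
TSP	H	0.0	9			5.0	reference	0.8
tartrate	H	4.47	2			40.0	metabolite	0.5
lactate	CH3	1.33	3	CH	6.9	30.0	metabolite	0.5
lactate	CH	4.11	1	CH3	6.9	30.0	metabolite	0.5
acetate	H	1.91	3			30.0	metabolite	0.5
succinate	H	2.51	4			25.0	metabolite	0.5
alanine	CH3	1.48	3	CH	7.2	3.0	metabolite	0.5
alanine	CH	3.78	1	CH3	7.2	3.0	metabolite	0.5
isopentanol	CH3	0.9	6	CH2	6.6	8.0	metabolite	0.5
isopentanol	CH2	1.45	2	CH3	6.6	8.0	metabolite	0.5
isopentanol	CH2	1.45	2	OCH2	6.9	8.0	metabolite	0.5
isopentanol	OCH2	3.61	2	CH2	6.9	8.0	metabolite	0.5
isobutanol	CH3	0.88	6	CH2	6.7	7.0	metabolite	0.5
isobutanol	CH2	3.35	2	CH3	6.7	7.0	metabolite	0.5
acetoin	CH3	1.37	3	CH	7.1	2.0	metabolite	0.5
acetoin	CH	4.41	1	CH3	7.1	2.0	metabolite	0.5
13-propanediol	CH2	1.78	2	OCH2	6.4	6.0	metabolite	0.5
13-propanediol	OCH2	3.67	4	CH2	6.4	6.0	metabolite	0.5
myo-inositol	H2	4.05	1	H13	2.8	2.5	metabolite	0.5
myo-inositol	H13	3.52	2	H2	2.8	2.5	metabolite	0.5
23-butanediol	CH3	1.14	6	CH	6.3	2.5	metabolite	0.5
23-butanediol	CH	3.73	2	CH3	6.3	2.5	metabolite	0.5
ethyl-acetate	CH3	1.26	3	OCH2	7.1	4.0	metabolite	0.5
ethyl-acetate	OCH2	4.12	2	CH3	7.1	4.0	metabolite	0.5
proline	Hg	2.0	2	Hd	6.8	1.2	metabolite	0.5
proline	Hd	3.38	2	Hg	6.8	1.2	metabolite	0.5
methanol	H	3.34	3			6.0	metabolite	0.5
choline	H	3.19	9			3.0	metabolite	0.5
glycerol	CH	3.78	1	CH2	6.0	8.0	metabolite	0.5
glycerol	CH2	3.56	4	CH	6.0	8.0	metabolite	0.5
ethanolamine	NCH2	3.14	2	OCH2	5.2	1.5	metabolite	0.5
ethanolamine	OCH2	3.82	2	NCH2	5.2	1.5	metabolite	0.5
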