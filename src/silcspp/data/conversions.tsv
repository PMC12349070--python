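nr	short	name	composition	elution_order	labeled_carbons	printed_delta
1	Red.neg	reduction	H2	1	0	2.0157
2	Met	methylation	CH2	2	0	14.0157
3	Oxy	oxygenation	O	1	0	15.9949
4	Hydr	hydration	H2O	1	0	18.0106
5	Mox	methoxylation	CH2O	2	0	30.0106
6	Ace	acetylation	C2H2O	2	0	42.0106
7	Tar	tartarate	C4H4O5	1	0	132.0060
8	anhydroGlc	1,6-anhydroglucose	C6H8O4	1	0	144.0423
9	Rha	deoxyhexose	C6H10O4	1	0	146.0579
10	Shi	shikimate	C7H8O4	1	0	156.0420
11	Hex	hexose	C6H10O5	1	0	162.0528
	Hex.AA	hexose and acetic acid adduct	C8H14O7	1	0	222.0740
12	Qui	quinate	C7H10O5	1	0	174.0530
13	GlcA	hexaric acid	C6H8O7	1	0	192.0270
14	Box	beta-oxidation	C2H2	1	0	26.0157
	Box.13C2	beta-oxidation.13C2	C2H2	1	2	28.0224
15	Ben	benzoic acid	C7H4O	2	0	104.0262
	Ben.13C	benzoic acid.13C	C7H4O	2	1	104.0262
16	Phb	hydroxybenzoic acid	C7H4O2	2	0	120.0211
	Phb.13C	hydroxybenzoic acid.13C1	C7H4O2	2	1	121.0245
17	Cou	coumarate	C9H6O2	2	0	146.0368
	Cou.13C3	coumarate.13C3	C9H6O2	2	3	149.0469
18	Van	vanillic acid	C8H6O3	2	0	150.0317
	Van.13C	vanillic acid.13C	C8H6O3	2	1	151.0350
19	Caf	caffeate	C9H6O3	2	0	162.0317
	Caf.13C3	caffeate.13C3	C9H6O3	2	3	165.0418
20	Fer	ferulate	C10H8O3	2	0	176.0473
	Fer.13C3	ferulate.13C3	C10H8O3	2	3	179.0574
21	condGun	condensed.guaiacyl	C10H10O3	2	0	178.0630
	condGun.13C3	condensed.guaiacyl.13C3	C10H10O3	2	3	181.0731
22	Gun	guaiacyl	C10H12O4	2	0	196.0736
	Gun.13C3	guaiacyl.13C3	C10H12O4	2	3	199.0837
23	Sin	sinapate	C11H10O4	2	0	206.0579
	Sin.13C3	sinapate.13C3	C11H10O4	2	3	209.0680
24	condSun	condensed.syringyl	C11H12O4	2	0	208.0735
	condSun.13C3	condensed.syringyl.13C3	C11H12O4	2	3	211.0836
25	Sun	syringyl	C11H14O5	2	0	226.0841
	Sun.13C3	syringyl.13C3	C11H14O5	2	3	229.0942
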