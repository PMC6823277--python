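positive_site	condition	residue_occupancy_pct	chloride_occupancy_pct
N-terminal	Charmm27_tip3p	111.8	0.4
N-terminal	Amber99sb_spce	129.2	1.7
N-terminal	Amber99sb_tip3p	102.7	2.1
N-terminal	Amber14sb_tip3p	97.7	0.8
N-terminal	Gromos43a1_spce	137.3	0.6
N-terminal	Gromos53a6_spce	127.3	0.2
Lys16	Charmm27_tip3p	30.6	10.1
Lys16	Amber99sb_spce	30.7	7.8
Lys16	Amber99sb_tip3p	35.0	5.9
Lys16	Amber14sb_tip3p	41.6	6.1
Lys16	Gromos43a1_spce	55.1	4.0
Lys16	Gromos53a6_spce	48.6	4.7
Lys19	Charmm27_tip3p	162.7	7.4
Lys19	Amber99sb_spce	163.3	4.2
Lys19	Amber99sb_tip3p	187.0	2.6
Lys19	Amber14sb_tip3p	149.2	4.2
Lys19	Gromos43a1_spce	126.4	4.1
Lys19	Gromos53a6_spce	122.4	5.2
Lys23	Charmm27_tip3p	4.3	14.7
Lys23	Amber99sb_spce	1.2	13.1
Lys23	Amber99sb_tip3p	1.4	8.4
Lys23	Amber14sb_tip3p	7.5	9.8
Lys23	Gromos43a1_spce	6.6	8.3
Lys23	Gromos53a6_spce	8.4	10.2
Arg25	Charmm27_tip3p	97.3	2.3
Arg25	Amber99sb_spce	96.2	1.7
Arg25	Amber99sb_tip3p	91.3	1.3
Arg25	Amber14sb_tip3p	99.4	1.5
Arg25	Gromos43a1_spce	92.4	0.9
Arg25	Gromos53a6_spce	96.8	0.4
Arg33	Charmm27_tip3p	0.0	99.9
Arg33	Amber99sb_spce	1.6	58.8
Arg33	Amber99sb_tip3p	3.9	62.1
Arg33	Amber14sb_tip3p	0.0	99.8
Arg33	Gromos43a1_spce	121.3	13.2
Arg33	Gromos53a6_spce	73.5	18.0
Arg36	Charmm27_tip3p	132.0	5.8
Arg36	Amber99sb_spce	133.9	2.0
Arg36	Amber99sb_tip3p	147.3	1.4
Arg36	Amber14sb_tip3p	93.8	3.6
Arg36	Gromos43a1_spce	104.8	6.3
Arg36	Gromos53a6_spce	87.6	8.5
Lys44	Charmm27_tip3p	84.5	6.7
Lys44	Amber99sb_spce	62.0	6.9
Lys44	Amber99sb_tip3p	54.7	5.6
Lys44	Amber14sb_tip3p	40.6	5.5
Lys44	Gromos43a1_spce	48.6	6.4
Lys44	Gromos53a6_spce	62.7	6.2
Lys49	Charmm27_tip3p	90.3	10.4
Lys49	Amber99sb_spce	122.5	4.6
Lys49	Amber99sb_tip3p	96.1	3.8
Lys49	Amber14sb_tip3p	60.2	7.0
Lys49	Gromos43a1_spce	134.9	7.2
Lys49	Gromos53a6_spce	83.2	10.4
Arg58	Charmm27_tip3p	132.5	1.1
Arg58	Amber99sb_spce	134.4	0.4
Arg58	Amber99sb_tip3p	130.6	0.3
Arg58	Amber14sb_tip3p	147.0	0.5
Arg58	Gromos43a1_spce	102.4	2.6
Arg58	Gromos53a6_spce	111.5	1.8
Lys66	Charmm27_tip3p	135.0	2.0
Lys66	Amber99sb_spce	139.7	1.6
Lys66	Amber99sb_tip3p	146.0	1.4
Lys66	Amber14sb_tip3p	177.8	0.9
Lys66	Gromos43a1_spce	144.9	0.6
Lys66	Gromos53a6_spce	102.9	0.9
Arg68	Charmm27_tip3p	193.9	4.9
Arg68	Amber99sb_spce	195.5	1.9
Arg68	Amber99sb_tip3p	195.6	2.2
Arg68	Amber14sb_tip3p	208.5	2.3
Arg68	Gromos43a1_spce	143.7	1.0
Arg68	Gromos53a6_spce	117.0	1.6
Lys70	Charmm27_tip3p	92.1	3.0
Lys70	Amber99sb_spce	85.7	1.7
Lys70	Amber99sb_tip3p	87.8	1.9
Lys70	Amber14sb_tip3p	106.3	1.9
Lys70	Gromos43a1_spce	123.8	0.9
Lys70	Gromos53a6_spce	95.0	1.5
Arg82	Charmm27_tip3p	171.6	1.6
Arg82	Amber99sb_spce	218.1	0.6
Arg82	Amber99sb_tip3p	220.9	1.0
Arg82	Amber14sb_tip3p	230.3	1.2
Arg82	Gromos43a1_spce	188.4	0.4
Arg82	Gromos53a6_spce	242.6	0.4
Lys94	Charmm27_tip3p	60.7	6.2
Lys94	Amber99sb_spce	82.7	3.0
Lys94	Amber99sb_tip3p	89.3	3.1
Lys94	Amber14sb_tip3p	53.4	4.3
Lys94	Gromos43a1_spce	78.0	3.6
Lys94	Gromos53a6_spce	53.6	3.6
Lys101	Charmm27_tip3p	136.3	3.0
Lys101	Amber99sb_spce	150.4	1.7
Lys101	Amber99sb_tip3p	138.8	1.7
Lys101	Amber14sb_tip3p	88.6	3.0
Lys101	Gromos43a1_spce	62.4	3.0
Lys101	Gromos53a6_spce	36.4	3.5
Lys102	Charmm27_tip3p	51.7	6.3
Lys102	Amber99sb_spce	47.5	4.7
Lys102	Amber99sb_tip3p	45.3	4.5
Lys102	Amber14sb_tip3p	58.9	4.3
Lys102	Gromos43a1_spce	128.9	2.0
Lys102	Gromos53a6_spce	100.4	2.0
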