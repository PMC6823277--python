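positive_site	partner	Charmm27_tip3p	Amber99sb_spce	Amber99sb_tip3p	Amber14sb_tip3p	Gromos43a1_spce	Gromos53a6_spce
Lys19	Glu46	0.0	0.1	0.0	0.0	1.1	0.1
Lys19	Glu47	72.3	69.1	91.6	57.4	35.2	32.2
Lys23	Glu42	0.0	0.0	0.0	0.0	0.2	0.0
Arg25	Glu42	0.0	0.0	0.0	0.0	2.3	0.8
Arg33	Glu34	0.0	0.7	3.7	0.0	66.5	38.3
Arg33	Glu47	0.0	0.0	0.0	0.0	0.0	0.0
Arg36	Glu15	33.2	53.1	64.9	34.3	34.1	13.1
Arg36	Glu34	0.1	0.0	0.1	0.4	3.4	3.2
Lys44	Glu15	0.0	0.0	0.0	0.0	0.1	0.0
Lys56	Glu50	0.2	12.6	0.3	0.0	59.7	13.9
Lys66	Asp87	30.3	46.0	51.8	63.5	25.8	11.1
Lys66	Glu90	44.9	9.6	12.4	17.1	28.6	36.5
Lys66	Asp91	0.0	0.0	0.0	0.0	0.0	0.1
Lys70	Glu90	2.2	1.2	1.1	18.6	10.1	9.5
Lys70	Asp91	57.1	11.0	22.6	44.1	58.5	56.4
Arg82	Asp86	24.8	98.0	99.8	57.9	90.3	8.5
Arg82	Asp87	19.3	71.7	70.1	45.9	39.5	88.2
Lys101	Glu42	0.0	0.0	0.0	0.0	0.3	0.3
Lys102	Glu42	0.0	0.0	0.0	0.0	0.4	0.1
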