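positive_site	partner	Charmm27_tip3p	Amber99sb_spce	Amber99sb_tip3p	Amber14sb_tip3p	Gromos43a1_spce	Gromos53a6_spce
N-terminal	Glu59	97.7	84.3	61.0	95.0	98.4	98.9
N-terminal	Asp84	13.5	44.9	41.7	2.7	37.6	15.1
N-terminal	Asp86	0.7	0.0	0.0	0.0	1.3	13.4
Lys16	Asp10	0.0	0.1	0.0	0.0	0.0	0.0
Lys16	Glu12	28.6	29.4	32.9	40.3	54.2	47.8
Lys16	Glu15	2.0	1.2	2.1	1.3	0.9	0.8
Lys19	Glu12	0.0	0.0	0.0	0.0	0.0	0.0
Lys19	Glu15	90.4	94.0	95.4	91.8	90.1	90.1
Lys23	Glu24	4.3	1.2	1.4	7.5	6.4	8.3
Arg25	Glu24	0.0	0.0	0.0	0.0	0.3	0.0
Arg25	Glu98	0.0	0.1	0.0	0.1	0.4	0.0
Arg25	Glu99	97.2	96.1	91.3	99.3	86.5	94.9
Arg25	C-terminal	0.0	0.0	0.0	0.0	2.9	1.1
Arg33	Glu34	0.0	0.9	0.2	0.0	54.8	35.3
Arg36	Glu34	0.0	0.3	0.1	0.1	0.3	0.1
Arg36	Glu46	0.0	0.0	0.0	0.0	0.0	0.0
Arg36	Glu47	89.9	74.9	79.5	56.7	65.8	71.1
Arg36	Asp48	8.8	5.6	2.8	2.3	1.2	0.2
Lys44	Glu42	19.6	12.2	14.4	8.3	5.6	1.8
Lys44	Glu46	64.9	49.8	40.4	32.2	41.0	60.4
Lys44	Glu47	0.0	0.0	0.0	0.1	1.8	0.5
Lys49	Asp10	5.0	4.3	6.0	0.4	7.8	0.8
Lys49	Glu12	0.0	0.0	0.0	0.0	0.0	0.0
Lys49	Glu34	82.6	92.2	84.3	56.9	50.5	63.4
Lys49	Glu47	0.6	0.1	0.1	0.5	8.9	2.8
Lys49	Asp48	1.9	13.4	5.3	2.5	8.0	2.4
Arg58	Glu59	0.2	0.0	0.3	0.2	5.4	1.4
Arg58	Asp60	99.9	98.5	99.8	99.8	79.5	93.0
Arg58	Glu98	0.0	0.0	0.0	0.0	0.8	0.0
Arg58	C-terminal	32.4	35.9	30.6	47.0	16.7	17.1
Lys66	Glu63	52.3	60.0	72.2	89.0	71.2	44.3
Lys66	Glu67	7.5	24.1	9.6	8.2	19.3	11.0
Arg68	Glu24	99.5	99.5	95.6	53.7	58.2	63.2
Arg68	Glu64	9.0	3.0	3.5	37.4	24.4	19.6
Arg68	Glu67	1.8	0.7	3.5	45.3	14.5	6.4
Arg68	Glu71	83.6	92.2	93.0	72.1	46.4	27.8
Arg68	C-terminal	0.0	0.0	0.0	0.0	0.2	0.0
Lys70	Glu63	0.0	0.0	0.0	0.0	0.0	0.0
Lys70	Glu67	29.8	54.5	46.3	40.1	50.0	26.5
Lys70	Glu71	2.7	1.0	1.9	3.0	4.3	2.2
Lys70	Asp76	0.3	18.1	15.9	0.5	0.9	0.4
Arg82	Glu59	27.9	46.0	50.0	45.7	51.7	58.9
Arg82	Asp60	0.0	0.0	0.0	0.0	0.0	0.0
Arg82	Glu63	0.0	0.0	0.1	0.0	0.1	0.0
Arg82	Asp84	99.6	2.3	1.1	80.8	6.7	86.8
Lys94	Glu90	27.2	43.2	43.5	20.5	31.7	16.7
Lys94	Asp91	26.0	28.9	41.7	25.5	35.1	21.1
Lys94	Glu98	7.4	10.5	4.1	7.4	10.8	15.8
Lys94	Glu99	0.0	0.0	0.0	0.0	0.3	0.0
Lys101	Glu24	10.8	10.4	12.6	15.6	3.7	4.2
Lys101	Asp60	0.0	0.0	0.0	0.0	4.3	1.2
Lys101	Glu64	86.8	88.0	80.2	14.5	7.7	6.5
Lys101	Glu98	0.0	0.0	0.0	0.0	32.9	10.1
Lys101	Glu99	0.0	0.0	0.0	0.0	4.0	6.9
Lys101	C-terminal	38.7	52.0	46.0	58.6	9.7	7.2
Lys102	Glu24	0.0	0.0	0.0	0.0	4.4	4.5
Lys102	Glu59	0.0	0.0	0.0	0.0	0.0	0.0
Lys102	Asp60	0.5	0.3	0.4	0.2	37.3	29.6
Lys102	Glu63	0.0	0.0	0.0	0.0	1.5	0.6
Lys102	Glu64	0.0	0.1	0.0	0.1	59.1	54.0
Lys102	Glu98	51.2	47.2	44.9	58.7	19.4	6.9
Lys102	Glu99	0.0	0.0	0.0	0.0	6.8	4.6
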