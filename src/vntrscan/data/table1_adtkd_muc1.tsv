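# Clinical characteristics of the 19 ADTKD-MUC1 cases diagnosed by long-read
# sequencing (transcribed published cohort table).
# egfr: mL/min/1.73m2, or "RRT (<age> y)" when renal replacement therapy had
# already started at diagnosis.  urinary_protein: g/gCr, or negative/ND/Auria.
id	age_at_diagnosis	sex	family_history	pathology	hypertension	hyperuricemia	egfr	urinary_protein	serum_potassium
SC370	48	M	+	-	-	ND	RRT (32 y)	0.03	4.1
SC416	33	M	+	Chronic TIN	-	+ (29 y)	23	1.6	4.6
SC489	54	M	+	Chronic damage of interstitium	+ (54 y)	+ (53 y)	6.5	1.4	5.6
SC534	41	F	+	MCKD	+ (40 y)	-	RRT (40 y)	0.27	3.9
SC656	46	F	+	-	+ (40 y)	+ (ND)	41	0.12	4
SC512	37	M	-	MCKD	-	+ (ND)	16.4	0.31	4.8
SC566	50	M	-	MCKD	+ (42 y)	-	10	0.27	3.8
SC265	43	F	+	Global sclerosis	-	-	34.8	negative	5.4
SC359	39	M	+	MCKD	+ (36 y)	+ (34 y)	40	1.6	4.1
SC696	48	F	+	-	+	-	9.9	0.05	5.1
SC732	68	F	+	-	+ (50 y)	-	RRT (65 y)	ND	4
SC798	48	F	+	MGA	ND	ND	RRT (48 y)	1.38	4.48
SC870	25	M	+	-	+ (23 y)	ND	24.5	0	4.8
SC874	40	M	+	-	-	-	RRT (31 y)	Auria	4.2
SC912	39	F	+	MCKD	-	-	22	Negative	4.8
SC973	26	F	+	MCKD	+ (26 y)	-	49.2	0.1	4.3
SC995	46	M	+	-	+ (around 20 y)	+ (around 20 y)	RRT (46 y)	0.19	4.4
SC1079	26	M	+	MCKD	-	-	47	0.05	3.9
SC1112	31	M	+	MCKD	-	-	RRT (28 y)	1.52	4.9
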