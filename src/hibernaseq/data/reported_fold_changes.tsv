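tissue	gene	numerator	denominator	fold	lower_bound
heart	NAC1	Torpor	March	5.3	0
heart	PDK4	Torpor	October	8.0	0
heart	RYR2	Torpor	March	3.5	0
heart	NU1M	March	IBA	2.6	0
heart	CYB	March	IBA	2.4	0
heart	COX2	March	IBA	2.4	0
skeletal_muscle	SARCO	April	August	10.5	0
skeletal_muscle	GLNA	April	IBA	5.4	0
skeletal_muscle	KCRS	April	IBA	5.1	0
skeletal_muscle	TNNT1	April	August	2.9	0
skeletal_muscle	THIM	April	August	4.7	0
skeletal_muscle	UBC	October	March	2.3	0
skeletal_muscle	DDB1	October	August	1.6	0
skeletal_muscle	ASB2	October	April	3.6	0
skeletal_muscle	CCD69	October	IBA	2.3	0
skeletal_muscle	NDRG2	Torpor	April	3.3	0
skeletal_muscle	PDK4	Torpor	October	4.1	0
skeletal_muscle	HS90B	Torpor	August	1.4	0
skeletal_muscle	MAP4	Torpor	April	2.0	0
skeletal_muscle	NF2L1	Torpor	March	3.6	0
wat	ACOD	August	March	3.2	0
wat	FABP4	August	March	1.7	0
wat	LEP	October	March	6.4	0
wat	PAG16	October	August	2.2	0
wat	ALBU	October	all_other	21.8	1
wat	PDK4	IBA	October	4.3	0
wat	PCKGC	IBA	August	1.8	0
wat	ANXA8	IBA	March	3.4	0
wat	HMCS2	IBA	August	3.8	0
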