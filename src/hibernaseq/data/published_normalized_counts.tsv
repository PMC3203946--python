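gene	tissue	April	August	October	Torpor	IBA	March
MALAT1	skeletal_muscle	1883	943	1724	1961	1708	799
MALAT1	heart	2849	2834	5056	2345	1355	3039
MALAT1	wat	635	388	1636	412	448	367
ACODA	skeletal_muscle	4	29	11	3	1	1
ACODB	skeletal_muscle	2	6	2	11	7	2
ACOD	skeletal_muscle	7	38	14	14	12	4
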