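analyte	synonyms	specimen	unit	low	high	conversions	snomed_higher	snomed_lower	snomed_normal
WBC	白细胞	blood	10^9/L	4	10	/L:1e-9;10^9/L:1	414478003	84828003	
RBC	红细胞	blood	10^12/L	3.8	5.8	/L:1e-12;10^12/L:1	165551003	83157008	
hemoglobin	血红蛋白|Hb	blood	g/L	115	150	g/L:1;g/dL:10	165397008	271737000	
platelet	血小板|PLT	blood	10^9/L	100	300	/L:1e-9;10^9/L:1	6631009	302215000	
glucose	血糖|GLU	blood	mmol/L	3.9	6.1	mmol/L:1;mg/dL:0.0555	80394007	302866003	
CRP	C反应蛋白	blood	mg/L	0	8	mg/L:1	119971000		
ALT	谷丙转氨酶	blood	U/L	9	50	U/L:1	707724006		
body temperature	体温		°C	36.1	37.3	°C:1	386661006	386689009	
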