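surface	letter	category	normalization
疼痛	P		pain
发热	P		fever
咳嗽	P		cough
咳痰	P		expectoration
乏力	P		fatigue
腹痛	P		abdominal pain
腹泻	P		diarrhea
呼吸困难	P		dyspnea
头痛	P		headache
消瘦	P		weight loss
胸闷	P		chest tightness
没有出现	A	assertion	absent
无	A	assertion	absent
未见	A	assertion	absent
否认	A	assertion	absent
出现	A	assertion	present
剧烈	A	severity	severe
严重	A	severity	severe
轻微	A	severity	mild
轻度	A	severity	mild
中度	A	severity	moderate
突发	A	temporal pattern	acute
急性	A	temporal pattern	acute
慢性	A	temporal pattern	chronic
反复	A	temporal pattern	recurrent
偶尔	A	temporal pattern	occasional
偶有	A	temporal pattern	occasional
呈持续性	A	temporal pattern	persistent
持续性	A	temporal pattern	persistent
左侧	A	laterality	left
右侧	A	laterality	right
双侧	A	laterality	bilateral
弥漫性	A	spatial pattern	diffuse
局限性	A	spatial pattern	localized
放射性	A	spatial pattern	radiating
右下	A	quadrant pattern	right-lower
右上	A	quadrant pattern	right-upper
左下	A	quadrant pattern	left-lower
左上	A	quadrant pattern	left-upper
腹部	A	body location	abdomen
胸部	A	body location	chest
头部	A	body location	head
背部	A	body location	back
咽喉	A	body location	throat
血	S		blood
尿	S		urine
痰	S		sputum
白细胞	L		WBC
WBC	L		WBC
红细胞	L		RBC
RBC	L		RBC
血红蛋白	L		hemoglobin
血小板	L		platelet
糖	L		glucose
GLU	L		glucose
C反应蛋白	L		CRP
CRP	L		CRP
谷丙转氨酶	L		ALT
ALT	L		ALT
体温	L		body temperature
升高	R		higher
增高	R		higher
偏高	R		higher
降低	R		lower
减少	R		lower
偏低	R		lower
正常	R		normal
/L	U		/L
10^9/L	U		10^9/L
10^12/L	U		10^12/L
g/L	U		g/L
g/dL	U		g/dL
mmol/L	U		mmol/L
mg/dL	U		mg/dL
mg/L	U		mg/L
U/L	U		U/L
°C	U		°C
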