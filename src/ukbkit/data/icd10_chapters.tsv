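chapter	block_start	block_end	description
1	A00	B99	Certain infectious and parasitic diseases
2	C00	D48	Neoplasms
3	D50	D89	Diseases of the blood and blood-forming organs and certain disorders involving the immune mechanism
4	E00	E90	Endocrine, nutritional and metabolic diseases
5	F00	F99	Mental and behavioural disorders
6	G00	G99	Diseases of the nervous system
7	H00	H59	Diseases of the eye and adnexa
8	H60	H95	Diseases of the ear and mastoid process
9	I00	I99	Diseases of the circulatory system
10	J00	J99	Diseases of the respiratory system
11	K00	K93	Diseases of the digestive system
12	L00	L99	Diseases of the skin and subcutaneous tissue
13	M00	M99	Diseases of the musculoskeletal system and connective tissue
14	N00	N99	Diseases of the genitourinary system
15	O00	O99	Pregnancy, childbirth and the puerperium
16	P00	P96	Certain conditions originating in the perinatal period
17	Q00	Q99	Congenital malformations, deformations and chromosomal abnormalities
18	R00	R99	Symptoms, signs and abnormal clinical and laboratory findings, not elsewhere classified
19	S00	T98	Injury, poisoning and certain other consequences of external causes
20	V01	Y98	External causes of morbidity and mortality
21	Z00	Z99	Factors influencing health status and contact with health services
22	U00	U85	Codes for special purposes
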