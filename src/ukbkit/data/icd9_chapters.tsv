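chapter	block_start	block_end	description
1	001	139	Infectious and parasitic diseases
2	140	239	Neoplasms
3	240	279	Endocrine, nutritional and metabolic diseases, and immunity disorders
4	280	289	Diseases of the blood and blood-forming organs
5	290	319	Mental disorders
6	320	389	Diseases of the nervous system and sense organs
7	390	459	Diseases of the circulatory system
8	460	519	Diseases of the respiratory system
9	520	579	Diseases of the digestive system
10	580	629	Diseases of the genitourinary system
11	630	679	Complications of pregnancy, childbirth, and the puerperium
12	680	709	Diseases of the skin and subcutaneous tissue
13	710	739	Diseases of the musculoskeletal system and connective tissue
14	740	759	Congenital anomalies
15	760	779	Certain conditions originating in the perinatal period
16	780	799	Symptoms, signs, and ill-defined conditions
17	800	999	Injury and poisoning
18	V01	V91	Supplementary classification of factors influencing health status and contact with health services
19	E000	E999	Supplementary classification of external causes of injury and poisoning
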