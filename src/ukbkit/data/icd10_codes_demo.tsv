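code	description
A00	Cholera
A09	Diarrhoea and gastroenteritis of presumed infectious origin
B20	Human immunodeficiency virus [HIV] disease resulting in infectious and parasitic diseases
B99	Other and unspecified infectious diseases
C34	Malignant neoplasm of bronchus and lung
C50	Malignant neoplasm of breast
D50	Iron deficiency anaemia
D64	Other anaemias
E10	Insulin-dependent diabetes mellitus
E11	Non-insulin-dependent diabetes mellitus
E66	Obesity
F32	Depressive episode
F41	Other anxiety disorders
G40	Epilepsy
G43	Migraine
H25	Senile cataract
H65	Nonsuppurative otitis media
I00	Rheumatic fever without mention of heart involvement
I05	Rheumatic mitral valve diseases
I10	Essential (primary) hypertension
I11	Hypertensive heart disease
I20	Angina pectoris
I21	Acute myocardial infarction
I210	Acute transmural myocardial infarction of anterior wall
I219	Acute myocardial infarction, unspecified
I22	Subsequent myocardial infarction
I23	Certain current complications following acute myocardial infarction
I24	Other acute ischaemic heart diseases
I25	Chronic ischaemic heart disease
I251	Atherosclerotic heart disease
I259	Chronic ischaemic heart disease, unspecified
I26	Pulmonary embolism
I42	Cardiomyopathy
I420	Dilated cardiomyopathy
I46	Cardiac arrest
I48	Atrial fibrillation and flutter
I50	Heart failure
I51	Complications and ill-defined descriptions of heart disease
I516	Cardiovascular disease, unspecified
I60	Subarachnoid haemorrhage
I61	Intracerebral haemorrhage
I62	Other nontraumatic intracranial haemorrhage
I63	Cerebral infarction
I64	Stroke, not specified as haemorrhage or infarction
I65	Occlusion and stenosis of precerebral arteries, not resulting in cerebral infarction
I66	Occlusion and stenosis of cerebral arteries, not resulting in cerebral infarction
I67	Other cerebrovascular diseases
I68	Cerebrovascular disorders in diseases classified elsewhere
I69	Sequelae of cerebrovascular disease
I70	Atherosclerosis
I73	Other peripheral vascular diseases
I74	Arterial embolism and thrombosis
I740	Embolism and thrombosis of abdominal aorta
I743	Embolism and thrombosis of arteries of lower extremities
I80	Phlebitis and thrombophlebitis
I83	Varicose veins of lower extremities
I99	Other and unspecified disorders of circulatory system
J09	Influenza due to identified zoonotic or pandemic influenza virus
J10	Influenza due to other identified influenza virus
J11	Influenza, virus not identified
J12	Viral pneumonia, not elsewhere classified
J13	Pneumonia due to Streptococcus pneumoniae
J14	Pneumonia due to Haemophilus influenzae
J15	Bacterial pneumonia, not elsewhere classified
J16	Pneumonia due to other infectious organisms, not elsewhere classified
J17	Pneumonia in diseases classified elsewhere
J18	Pneumonia, organism unspecified
J189	Pneumonia, unspecified
J19	Bronchitis, not specified as acute or chronic
J20	Acute bronchitis
J21	Acute bronchiolitis
J22	Unspecified acute lower respiratory infection
J44	Other chronic obstructive pulmonary disease
J45	Asthma
K21	Gastro-oesophageal reflux disease
K29	Gastritis and duodenitis
K80	Cholelithiasis
L40	Psoriasis
M16	Coxarthrosis [arthrosis of hip]
M54	Dorsalgia
N18	Chronic renal failure
N39	Other disorders of urinary system
O80	Single spontaneous delivery
P23	Congenital pneumonia
P96	Other conditions originating in the perinatal period
Q21	Congenital malformations of cardiac septa
R07	Pain in throat and chest
R51	Headache
S72	Fracture of femur
T98	Sequelae of other and unspecified effects of external causes
V01	Pedestrian injured in collision with pedal cycle
W19	Unspecified fall
Y98	Lifestyle-related condition
Z00	General examination and investigation of persons without complaint and reported diagnoses
Z51	Other medical care
U04	Severe acute respiratory syndrome [SARS]
U85	Resistance to antineoplastic drugs
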