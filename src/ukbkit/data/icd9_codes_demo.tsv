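code	description
001	Cholera
008	Intestinal infections due to other organisms
140	Malignant neoplasm of lip
162	Malignant neoplasm of trachea, bronchus, and lung
250	Diabetes mellitus
2500	Diabetes mellitus without mention of complication
278	Overweight, obesity and other hyperalimentation
285	Other and unspecified anemias
296	Episodic mood disorders
345	Epilepsy and recurrent seizures
346	Migraine
390	Rheumatic fever without mention of heart involvement
401	Essential hypertension
410	Acute myocardial infarction
4109	Acute myocardial infarction of unspecified site
411	Other acute and subacute forms of ischemic heart disease
413	Angina pectoris
414	Other forms of chronic ischemic heart disease
425	Cardiomyopathy
427	Cardiac dysrhythmias
428	Heart failure
430	Subarachnoid hemorrhage
431	Intracerebral hemorrhage
434	Occlusion of cerebral arteries
436	Acute, but ill-defined, cerebrovascular disease
444	Arterial embolism and thrombosis
459	Other disorders of circulatory system
480	Viral pneumonia
481	Pneumococcal pneumonia
486	Pneumonia, organism unspecified
487	Influenza
490	Bronchitis, not specified as acute or chronic
493	Asthma
530	Diseases of esophagus
571	Chronic liver disease and cirrhosis
599	Other disorders of urethra and urinary tract
715	Osteoarthrosis and allied disorders
724	Other and unspecified disorders of back
780	General symptoms
820	Fracture of neck of femur
V01	Contact with or exposure to communicable diseases
V70	General medical examination
E880	Fall on or from stairs or steps
E999	Late effect of injury due to war operations and terrorism
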