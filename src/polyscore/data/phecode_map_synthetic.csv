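icd_code,vocabulary,phecode,phenotype,category
110.9,ICD9CM,110.1,Dermatophytosis,infectious diseases
B35.9,ICD10CM,110.1,Dermatophytosis,infectious diseases
211.3,ICD9CM,208,Benign neoplasm of colon,neoplasms
D12.6,ICD10CM,208,Benign neoplasm of colon,neoplasms
250.00,ICD9CM,250.2,Type 2 diabetes,endocrine/metabolic
E11.9,ICD10CM,250.2,Type 2 diabetes,endocrine/metabolic
250.50,ICD9CM,250.7,Diabetic retinopathy,endocrine/metabolic
E11.319,ICD10CM,250.7,Diabetic retinopathy,endocrine/metabolic
272.4,ICD9CM,272.1,Hyperlipidemia,endocrine/metabolic
E78.5,ICD10CM,272.1,Hyperlipidemia,endocrine/metabolic
285.21,ICD9CM,285.21,Anemia in chronic kidney disease,hematopoietic
D63.1,ICD10CM,285.21,Anemia in chronic kidney disease,hematopoietic
305.1,ICD9CM,318,Tobacco use disorder,mental disorders
F17.200,ICD10CM,318,Tobacco use disorder,mental disorders
355.9,ICD9CM,351,Other peripheral nerve disorders,neurological
G62.9,ICD10CM,351,Other peripheral nerve disorders,neurological
366.10,ICD9CM,366.2,Senile cataract,sense organs
H25.9,ICD10CM,366.2,Senile cataract,sense organs
401.9,ICD9CM,401.1,Essential hypertension,circulatory system
I10,ICD10CM,401.1,Essential hypertension,circulatory system
518.81,ICD9CM,509.1,Respiratory failure,respiratory
J96.90,ICD10CM,509.1,Respiratory failure,respiratory
536.3,ICD9CM,536.3,Gastroparesis,digestive
K31.84,ICD10CM,536.3,Gastroparesis,digestive
585.3,ICD9CM,585.3,Chronic renal failure,genitourinary
N18.3,ICD10CM,585.3,Chronic renal failure,genitourinary
648.83,ICD9CM,649.1,Abnormal glucose tolerance complicating pregnancy,pregnancy complications
O24.419,ICD10CM,649.1,Abnormal glucose tolerance complicating pregnancy,pregnancy complications
707.10,ICD9CM,707.2,Chronic ulcer of leg or foot,dermatologic
L97.909,ICD10CM,707.2,Chronic ulcer of leg or foot,dermatologic
730.00,ICD9CM,710.11,Acute osteomyelitis,musculoskeletal
M86.9,ICD10CM,710.11,Acute osteomyelitis,musculoskeletal
746.9,ICD9CM,747.1,Cardiac congenital anomalies,congenital anomalies
Q24.9,ICD10CM,747.1,Cardiac congenital anomalies,congenital anomalies
782.3,ICD9CM,782.3,Edema,symptoms
R60.9,ICD10CM,782.3,Edema,symptoms
892.0,ICD9CM,871.3,Open wound of foot,injuries & poisonings
S91.309A,ICD10CM,871.3,Open wound of foot,injuries & poisonings
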