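patient_id,visit_id,visit_index,race,age_at_visit,icd9_code
P1,P1-v1,1,White,50,401.1
P1,P1-v1,1,White,50,250.00
P1,P1-v2,2,White,51,401.9
P2,P2-v1,1,White,40,780
P2,P2-v2,2,White,40,250
P3,P3-v1,1,White,61,780.2
P3,P3-v1,1,White,61,250
P4,P4-v1,1,White,30,272
P4,P4-v2,2,Asian,30,272
P5,P5-v1,1,,45,401
P5,P5-v2,2,,45,250
P6,P6-v1,1,Asian,35,296
P6,P6-v1,1,Asian,35,311
P6,P6-v2,2,Asian,36,296.0
P7,P7-v1,1,Asian,55,V27.0
P7,P7-v1,1,Asian,55,585.9
P8,P8-v1,1,Asian,28,401
P9,P9-v1,1,Asian,70,780
P10,P10-v1,1,White,44,493
P10,P10-v2,2,white,45,493
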