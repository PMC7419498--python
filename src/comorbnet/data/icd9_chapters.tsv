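chapter_id	name	lo	hi
1	infectious and parasitic diseases	1	139
2	neoplasms	140	239
3	endocrine, nutritional, metabolic and immunity	240	279
4	blood and blood-forming organs	280	289
5	mental disorders	290	319
6	nervous system	320	359
7	sense organs	360	389
8	circulatory system	390	459
9	respiratory system	460	519
10	digestive system	520	579
11	genitourinary system	580	629
12	pregnancy and childbirth complications	630	679
13	skin and subcutaneous tissue	680	709
14	musculoskeletal system and connective tissue	710	739
15	congenital anomalies	740	759
16	perinatal conditions	760	779
17	symptoms, signs and ill-defined conditions	780	799
18	injury and poisoning	800	999
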