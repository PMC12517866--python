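name	atc_code
ATORVASTATIN	C10AA05
ATORVASTATIN CALCIUM	C10AA05
ATORVASTATIN CALCIUM TRIHYDRATE	C10AA05
LIPITOR	C10AA05
ROSUVASTATIN	C10AA07
ROSUVASTATIN CALCIUM	C10AA07
CRESTOR	C10AA07
EZALLOR	C10AA07
SIMVASTATIN	C10AA01
ZOCOR	C10AA01
PRAVASTATIN	C10AA03
PRAVASTATIN SODIUM	C10AA03
FLUVASTATIN	C10AA04
PITAVASTATIN	C10AA08
LOVASTATIN	C10AA02
IBUPROFEN	M01AE01
ASPIRIN	B01AC06
ACETYLSALICYLIC ACID	B01AC06
METFORMIN	A10BA02
METFORMIN HYDROCHLORIDE	A10BA02
LISINOPRIL	C09AA03
OMEPRAZOLE	A02BC01
AMLODIPINE	C08CA01
AMLODIPINE BESYLATE	C08CA01
PARACETAMOL	N02BE01
ACETAMINOPHEN	N02BE01
LEVOTHYROXINE	H03AA01
LEVOTHYROXINE SODIUM	H03AA01
CLOPIDOGREL	B01AC04
PLAVIX	B01AC04
METOPROLOL	C07AB02
METOPROLOL TARTRATE	C07AB02
LOSARTAN	C09CA01
GABAPENTIN	N03AX12
SERTRALINE	N06AB06
PANTOPRAZOLE	A02BC02
FUROSEMIDE	C03CA01
WARFARIN	B01AA03
PREDNISONE	H02AB07
INSULIN GLARGINE	A10AE04
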