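pt_code	pt_name	soc_code	soc_name
10100001	Dyspnoea	10038738	Respiratory, thoracic and mediastinal disorders
10100002	Cough	10038738	Respiratory, thoracic and mediastinal disorders
10100003	Interstitial lung disease	10038738	Respiratory, thoracic and mediastinal disorders
10100004	Dyspnoea exertional	10038738	Respiratory, thoracic and mediastinal disorders
10100005	Oropharyngeal pain	10038738	Respiratory, thoracic and mediastinal disorders
10100006	Asthma	10038738	Respiratory, thoracic and mediastinal disorders
10100007	Wheezing	10038738	Respiratory, thoracic and mediastinal disorders
10100008	Bronchial irritation	10038738	Respiratory, thoracic and mediastinal disorders
10100009	Prolonged expiration	10038738	Respiratory, thoracic and mediastinal disorders
10100010	Pulmonary vascular disorder	10038738	Respiratory, thoracic and mediastinal disorders
10100011	Catarrh	10038738	Respiratory, thoracic and mediastinal disorders
10100012	Nasal oedema	10038738	Respiratory, thoracic and mediastinal disorders
10100013	Chronic respiratory disease	10038738	Respiratory, thoracic and mediastinal disorders
10100014	Epistaxis	10038738	Respiratory, thoracic and mediastinal disorders
10100015	Pulmonary embolism	10038738	Respiratory, thoracic and mediastinal disorders
10100016	Pleural effusion	10038738	Respiratory, thoracic and mediastinal disorders
10100017	Pneumonitis	10038738	Respiratory, thoracic and mediastinal disorders
10100018	Pulmonary oedema	10038738	Respiratory, thoracic and mediastinal disorders
10100019	Haemoptysis	10038738	Respiratory, thoracic and mediastinal disorders
10100020	Rhinorrhoea	10038738	Respiratory, thoracic and mediastinal disorders
10100021	Nasal congestion	10038738	Respiratory, thoracic and mediastinal disorders
10100022	Sinus congestion	10038738	Respiratory, thoracic and mediastinal disorders
10100023	Throat irritation	10038738	Respiratory, thoracic and mediastinal disorders
10100024	Productive cough	10038738	Respiratory, thoracic and mediastinal disorders
10100025	Hiccups	10038738	Respiratory, thoracic and mediastinal disorders
10100026	Sneezing	10038738	Respiratory, thoracic and mediastinal disorders
10100027	Dysphonia	10038738	Respiratory, thoracic and mediastinal disorders
10100028	Hypoxia	10038738	Respiratory, thoracic and mediastinal disorders
10100029	Respiratory failure	10038738	Respiratory, thoracic and mediastinal disorders
10100030	Respiratory distress	10038738	Respiratory, thoracic and mediastinal disorders
10100031	Acute respiratory failure	10038738	Respiratory, thoracic and mediastinal disorders
10100032	Pulmonary fibrosis	10038738	Respiratory, thoracic and mediastinal disorders
10100033	Pulmonary hypertension	10038738	Respiratory, thoracic and mediastinal disorders
10100034	Bronchospasm	10038738	Respiratory, thoracic and mediastinal disorders
10100035	Obstructive airways disorder	10038738	Respiratory, thoracic and mediastinal disorders
10100036	Chronic obstructive pulmonary disease	10038738	Respiratory, thoracic and mediastinal disorders
10100037	Sleep apnoea syndrome	10038738	Respiratory, thoracic and mediastinal disorders
10100038	Snoring	10038738	Respiratory, thoracic and mediastinal disorders
10100039	Laryngeal oedema	10038738	Respiratory, thoracic and mediastinal disorders
10100040	Pharyngeal oedema	10038738	Respiratory, thoracic and mediastinal disorders
10100041	Pleurisy	10038738	Respiratory, thoracic and mediastinal disorders
10100042	Pneumothorax	10038738	Respiratory, thoracic and mediastinal disorders
10100043	Atelectasis	10038738	Respiratory, thoracic and mediastinal disorders
10100044	Lung disorder	10038738	Respiratory, thoracic and mediastinal disorders
10100045	Lung infiltration	10038738	Respiratory, thoracic and mediastinal disorders
10100046	Orthopnoea	10038738	Respiratory, thoracic and mediastinal disorders
10100047	Tachypnoea	10038738	Respiratory, thoracic and mediastinal disorders
10100048	Bradypnoea	10038738	Respiratory, thoracic and mediastinal disorders
10100049	Hypoventilation	10038738	Respiratory, thoracic and mediastinal disorders
10100050	Hyperventilation	10038738	Respiratory, thoracic and mediastinal disorders
10100051	Apnoea	10038738	Respiratory, thoracic and mediastinal disorders
10100052	Nasal dryness	10038738	Respiratory, thoracic and mediastinal disorders
10100053	Paranasal sinus discomfort	10038738	Respiratory, thoracic and mediastinal disorders
10100054	Upper-airway cough syndrome	10038738	Respiratory, thoracic and mediastinal disorders
10100055	Allergic respiratory disease	10038738	Respiratory, thoracic and mediastinal disorders
10100056	Bronchiectasis	10038738	Respiratory, thoracic and mediastinal disorders
10100057	Laryngospasm	10038738	Respiratory, thoracic and mediastinal disorders
10100058	Mediastinal disorder	10038738	Respiratory, thoracic and mediastinal disorders
10100059	Pulmonary congestion	10038738	Respiratory, thoracic and mediastinal disorders
10100060	Respiratory tract congestion	10038738	Respiratory, thoracic and mediastinal disorders
10200001	Nausea	10017947	Gastrointestinal disorders
10200002	Vomiting	10017947	Gastrointestinal disorders
10200003	Diarrhoea	10017947	Gastrointestinal disorders
10200004	Abdominal pain	10017947	Gastrointestinal disorders
10200005	Constipation	10017947	Gastrointestinal disorders
10200006	Dyspepsia	10017947	Gastrointestinal disorders
10200007	Headache	10029205	Nervous system disorders
10200008	Dizziness	10029205	Nervous system disorders
10200009	Syncope	10029205	Nervous system disorders
10200010	Tremor	10029205	Nervous system disorders
10200011	Memory impairment	10029205	Nervous system disorders
10200012	Myalgia	10028395	Musculoskeletal and connective tissue disorders
10200013	Rhabdomyolysis	10028395	Musculoskeletal and connective tissue disorders
10200014	Arthralgia	10028395	Musculoskeletal and connective tissue disorders
10200015	Muscle spasms	10028395	Musculoskeletal and connective tissue disorders
10200016	Pain in extremity	10028395	Musculoskeletal and connective tissue disorders
10200017	Muscular weakness	10028395	Musculoskeletal and connective tissue disorders
10200018	Rash	10040785	Skin and subcutaneous tissue disorders
10200019	Pruritus	10040785	Skin and subcutaneous tissue disorders
10200020	Alopecia	10040785	Skin and subcutaneous tissue disorders
10200021	Urticaria	10040785	Skin and subcutaneous tissue disorders
10200022	Fatigue	10018065	General disorders and administration site conditions
10200023	Asthenia	10018065	General disorders and administration site conditions
10200024	Pyrexia	10018065	General disorders and administration site conditions
10200025	Oedema peripheral	10018065	General disorders and administration site conditions
10200026	Malaise	10018065	General disorders and administration site conditions
10200027	Drug ineffective	10018065	General disorders and administration site conditions
10200028	Hepatic enzyme increased	10022891	Investigations
10200029	Blood creatine phosphokinase increased	10022891	Investigations
10200030	Blood glucose increased	10022891	Investigations
10200031	Insomnia	10037175	Psychiatric disorders
10200032	Anxiety	10037175	Psychiatric disorders
10200033	Depression	10037175	Psychiatric disorders
10200034	Myocardial infarction	10007541	Cardiac disorders
10200035	Palpitations	10007541	Cardiac disorders
10200036	Atrial fibrillation	10007541	Cardiac disorders
10200037	Hypertension	10047065	Vascular disorders
10200038	Hypotension	10047065	Vascular disorders
10200039	Acute kidney injury	10038359	Renal and urinary disorders
10200040	Diabetes mellitus	10027433	Metabolism and nutrition disorders
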