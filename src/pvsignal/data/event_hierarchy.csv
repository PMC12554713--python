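pt,hlt,hlgt,soc
OSTEOPENIA,Metabolic bone disorders,Bone disorders,Musculoskeletal and connective tissue disorders
OSTEOPOROSIS,Metabolic bone disorders,Bone disorders,Musculoskeletal and connective tissue disorders
ARTHRALGIA,Joint related signs and symptoms,Joint disorders,Musculoskeletal and connective tissue disorders
BACK PAIN,Musculoskeletal and connective tissue pain,Musculoskeletal and connective tissue disorders NEC,Musculoskeletal and connective tissue disorders
MUSCLE SPASMS,Muscle related signs and symptoms,Muscle disorders,Musculoskeletal and connective tissue disorders
MYALGIA,Musculoskeletal and connective tissue pain,Musculoskeletal and connective tissue disorders NEC,Musculoskeletal and connective tissue disorders
SEIZURE,Seizures and seizure disorders,Seizures,Nervous system disorders
DIZZINESS,Neurological signs and symptoms,Neurological disorders NEC,Nervous system disorders
SOMNOLENCE,Disturbances in consciousness,Neurological disorders NEC,Nervous system disorders
HEADACHE,Headaches,Headaches,Nervous system disorders
TREMOR,Tremor,Movement disorders,Nervous system disorders
ATAXIA,Coordination and balance disturbances,Movement disorders,Nervous system disorders
MEMORY IMPAIRMENT,Memory loss,Mental impairment disorders,Nervous system disorders
FATIGUE,Asthenic conditions,General system disorders NEC,General disorders and administration site conditions
ASTHENIA,Asthenic conditions,General system disorders NEC,General disorders and administration site conditions
MALAISE,Feelings and sensations NEC,General system disorders NEC,General disorders and administration site conditions
DRUG INEFFECTIVE,Therapeutic and nontherapeutic responses,General system disorders NEC,General disorders and administration site conditions
PYREXIA,Febrile disorders,Body temperature conditions,General disorders and administration site conditions
GAIT DISTURBANCE,Gait disturbances,General system disorders NEC,General disorders and administration site conditions
NAUSEA,Nausea and vomiting symptoms,Gastrointestinal motility and defaecation conditions,Gastrointestinal disorders
VOMITING,Nausea and vomiting symptoms,Gastrointestinal motility and defaecation conditions,Gastrointestinal disorders
DIARRHOEA,Diarrhoea,Gastrointestinal motility and defaecation conditions,Gastrointestinal disorders
CONSTIPATION,Gastrointestinal atonic and hypomotility conditions,Gastrointestinal motility and defaecation conditions,Gastrointestinal disorders
RASH,Rashes eruptions and exanthems NEC,Epidermal and dermal conditions,Skin and subcutaneous tissue disorders
PRURITUS,Pruritus NEC,Epidermal and dermal conditions,Skin and subcutaneous tissue disorders
ALOPECIA,Alopecias,Hair and hair follicle conditions,Skin and subcutaneous tissue disorders
STEVENS-JOHNSON SYNDROME,Bullous conditions,Epidermal and dermal conditions,Skin and subcutaneous tissue disorders
DEPRESSION,Depressive disorders,Mood disorders and disturbances,Psychiatric disorders
CONFUSIONAL STATE,Confusion and disorientation,Deliria,Psychiatric disorders
AGGRESSION,Hostility and aggression,Behavioural disturbances,Psychiatric disorders
SUICIDAL IDEATION,Suicidal and self-injurious behaviour,Suicidal behaviours,Psychiatric disorders
INSOMNIA,Sleep disturbances,Sleep disorders,Psychiatric disorders
ANAEMIA,Anaemias NEC,Anaemias nonhaemolytic and marrow depression,Blood and lymphatic system disorders
THROMBOCYTOPENIA,Thrombocytopenias,Platelet disorders,Blood and lymphatic system disorders
HYPONATRAEMIA,Sodium imbalance,Electrolyte and fluid balance conditions,Metabolism and nutrition disorders
DECREASED APPETITE,Appetite disorders,Appetite and general nutritional disorders,Metabolism and nutrition disorders
WEIGHT INCREASED,Weight and body measurements,Investigations NEC,Investigations
BLOOD SODIUM DECREASED,Electrolyte analyses,Chemistry analyses,Investigations
BONE DENSITY DECREASED,Bone analyses,Musculoskeletal tissue analyses,Investigations
HEPATOTOXICITY,Hepatocellular damage conditions,Hepatic and hepatobiliary disorders,Hepatobiliary disorders
HEPATIC FUNCTION ABNORMAL,Hepatic function disorders,Hepatic and hepatobiliary disorders,Hepatobiliary disorders
ACUTE KIDNEY INJURY,Renal failure and impairment,Renal disorders,Renal and urinary disorders
FALL,Non-site specific injuries NEC,Injuries NEC,"Injury, poisoning and procedural complications"
VISION BLURRED,Visual disorders NEC,Vision disorders,Eye disorders
DIPLOPIA,Ocular motility disorders,Eye movement disorders,Eye disorders
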