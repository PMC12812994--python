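pt,soc
Neuropathy peripheral,Nervous system disorders
Polyneuropathy,Nervous system disorders
Paraesthesia,Nervous system disorders
Autonomic neuropathy,Nervous system disorders
Hypertensive encephalopathy,Nervous system disorders
Burning feet syndrome,Nervous system disorders
Neurotoxicity,Nervous system disorders
Peripheral sensory neuropathy,Nervous system disorders
Neuralgia,Nervous system disorders
Posterior reversible encephalopathy syndrome,Nervous system disorders
Guillain-Barre syndrome,Nervous system disorders
Peripheral motor neuropathy,Nervous system disorders
Peripheral sensorimotor neuropathy,Nervous system disorders
Dementia,Nervous system disorders
Neurological symptom,Nervous system disorders
Ataxia,Nervous system disorders
Myoclonus,Nervous system disorders
Chorea,Nervous system disorders
Post herpetic neuralgia,Nervous system disorders
Encephalopathy,Nervous system disorders
Headache,Nervous system disorders
Dizziness,Nervous system disorders
Intracranial mass,Nervous system disorders
Cauda equina syndrome,Nervous system disorders
Central nervous system haemorrhage,Nervous system disorders
Cerebral small vessel ischaemic disease,Nervous system disorders
Nausea,Gastrointestinal disorders
Vomiting,Gastrointestinal disorders
Diarrhoea,Gastrointestinal disorders
Constipation,Gastrointestinal disorders
Fatigue,General disorders and administration site conditions
Pyrexia,General disorders and administration site conditions
Asthenia,General disorders and administration site conditions
Oedema peripheral,General disorders and administration site conditions
Thrombocytopenia,Blood and lymphatic system disorders
Anaemia,Blood and lymphatic system disorders
Neutropenia,Blood and lymphatic system disorders
Pneumonia,Infections and infestations
Herpes zoster,Infections and infestations
Sepsis,Infections and infestations
Back pain,Musculoskeletal and connective tissue disorders
Muscular weakness,Musculoskeletal and connective tissue disorders
Arthralgia,Musculoskeletal and connective tissue disorders
Cardiac failure,Cardiac disorders
Atrial fibrillation,Cardiac disorders
Hypertension,Vascular disorders
Hypotension,Vascular disorders
Dyspnoea,"Respiratory, thoracic and mediastinal disorders"
Cough,"Respiratory, thoracic and mediastinal disorders"
Rash,Skin and subcutaneous tissue disorders
Pruritus,Skin and subcutaneous tissue disorders
Acute kidney injury,Renal and urinary disorders
Insomnia,Psychiatric disorders
Confusional state,Psychiatric disorders
Decreased appetite,Metabolism and nutrition disorders
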