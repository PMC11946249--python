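# SYNTHETIC MedDRA-style PT -> SOC hierarchy.
#
# MedDRA itself is licensed and cannot ship with the package.  This file is
# a synthetic stand-in covering every Preferred Term used by the bundled
# report generator, the DILI lexicon and the test suite, organised into the
# real SOC names.  Users with a MedDRA licence can point the pipeline at
# their own mapping file instead.
#
# Layout: SOC name -> list of PTs (matched case-insensitively).
gastrointestinal disorders:
  - nausea
  - vomiting
  - diarrhea
  - constipation
  - abdominal pain
  - dysphagia
  - oesophagitis
  - diverticulitis
  - gastrointestinal toxicity
general disorders and administration site conditions:
  - fatigue
  - pyrexia
  - oedema peripheral
  - oedema
  - death
  - disease progression
  - general physical health deterioration
  - fluid retention
  - drug resistance
nervous system disorders:
  - headache
  - dizziness
  - dysgeusia
  - cognitive disorder
  - speech disorder
  - amnesia
  - cerebral hemorrhage
  - brain oedema
  - central nervous system lesion
  - nervous system disorder
  - neuropathy peripheral
psychiatric disorders:
  - insomnia
  - anxiety
  - depression
  - hallucination
  - psychotic disorder
  - mental disorder
  - delirium
respiratory, thoracic and mediastinal disorders:
  - dyspnea
  - cough
  - pleural effusion
  - interstitial lung disease
  - pneumonitis
  - hemoptysis
  - pulmonary embolism
  - pulmonary oedema
  - lung disorder
  - respiratory failure
  - hypoxia
  - pulmonary toxicity
skin and subcutaneous tissue disorders:
  - rash
  - pruritus
  - photosensitivity reaction
musculoskeletal and connective tissue disorders:
  - arthralgia
  - myalgia
  - back pain
blood and lymphatic system disorders:
  - anemia
  - neutropenia
  - thrombocytopenia
  - hemolysis
  - hemolytic anemia
infections and infestations:
  - pneumonia
  - pneumonia bacterial
  - urinary tract infection
  - covid-19
neoplasms benign, malignant and unspecified (incl cysts and polyps):
  - malignant neoplasm progression
  - metastases to central nervous system
  - metastases to liver
  - metastases to bone
  - metastases to meninges
  - metastases to lung
metabolism and nutrition disorders:
  - decreased appetite
  - hypercholesterolemia
  - hyperglycemia
  - hypokalemia
  - hyperlipidemia
  - hypertriglyceridemia
  - dyslipidemia
investigations:
  - weight decreased
  - weight increased
  - blood creatinine increased
  - electrocardiogram qt prolonged
  - alanine aminotransferase increased
  - alt increased
  - aspartate aminotransferase increased
  - ast increased
  - transaminases increased
  - hepatic enzyme increased
  - hepatic enzyme abnormal
  - gamma-glutamyltransferase increased
  - blood alkaline phosphatase increased
  - blood bilirubin increased
  - bilirubin conjugated increased
  - liver function test abnormal
  - liver function test increased
  - ammonia increased
  - blood cholesterol increased
  - blood creatine phosphokinase increased
  - blood triglycerides increased
  - c-reactive protein increased
  - amylase increased
  - lipase increased
  - hemoglobin decreased
  - blood pressure increased
  - low-density lipoprotein increased
cardiac disorders:
  - cardiac failure
  - bradycardia
  - pericardial effusion
  - pericarditis
eye disorders:
  - photopsia
  - visual impairment
  - vitreous floaters
  - diplopia
renal and urinary disorders:
  - renal impairment
  - acute kidney injury
hepatobiliary disorders:
  - DILI
  - hepatic function abnormal
  - hepatotoxicity
  - liver injury
  - drug-induced liver injury
  - hepatocellular injury
  - hepatitis
  - hepatitis acute
  - hepatitis fulminant
  - hepatitis toxic
  - hepatitis cholestatic
  - autoimmune hepatitis
  - hepatic failure
  - acute hepatic failure
  - hepatic necrosis
  - hepatic cytolysis
  - hepatic steatosis
  - jaundice
  - jaundice cholestatic
  - cholestasis
  - liver disorder
  - hepatomegaly
  - hyperbilirubinemia
  - hyperbilirubinaemia
  - hepatic encephalopathy
  - hepatorenal syndrome
  - liver transplant
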