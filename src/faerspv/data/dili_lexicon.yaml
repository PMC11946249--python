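# Default lexicon of liver-injury Preferred Terms consolidated to the
# single event "DILI" before drug search.  Editable: the case definition
# is config-driven.  Entries are matched case-insensitively.
name: DILI
terms:
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
  - hyperbilirubinemia
  - hyperbilirubinaemia
  - liver function test abnormal
  - liver function test increased
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
  - hepatic encephalopathy
  - hepatorenal syndrome
  - ammonia increased
  - liver transplant
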