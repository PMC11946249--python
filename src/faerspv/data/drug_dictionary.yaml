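# Default drug dictionary for the five ALK tyrosine-kinase inhibitors.
# canonical id -> list of generic and brand-name spellings (matched
# case-insensitively after whitespace normalisation).
crizotinib:
  - crizotinib
  - xalkori
ceritinib:
  - ceritinib
  - zykadia
alectinib:
  - alectinib
  - alecensa
  - alecensaro
brigatinib:
  - brigatinib
  - alunbrig
lorlatinib:
  - lorlatinib
  - lorbrena
  - lorviqua
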