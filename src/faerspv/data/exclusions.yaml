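# Default PT exclusion lists applied only at the top-k ranking stage.
# Patterns are case-insensitive substrings.  The malignancy list is an
# explicit, editable choice: progression/metastasis terms are often the
# indication rather than a drug effect, but users may prefer to keep them.
death:
  - death
covid:
  - covid
malignancy:
  - malignant neoplasm progression
  - neoplasm progression
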