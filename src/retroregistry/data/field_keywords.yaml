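# Medical-field keyword lists: lowercase substrings matched (case-insensitive)
# against the free-text condition strings of a trial's registry record.
# Editable; an approximation of field classification by registry search.
cancer:
  - cancer
  - carcinoma
  - tumor
  - tumour
  - neoplasm
  - lymphoma
  - leukemia
  - leukaemia
  - melanoma
  - sarcoma
  - myeloma
  - glioma
  - metasta
cardiovascular:
  - cardiovascular
  - cardiac
  - heart
  - coronary
  - myocardial
  - hypertension
  - atrial fibrillation
  - atherosclerosis
  - heart failure
  - angina
neurological:
  - neurolog
  - alzheimer
  - parkinson
  - epilep
  - multiple sclerosis
  - stroke
  - dementia
  - neuropath
  - migraine
pain:
  - pain
  - analgesi
  - headache
  - migraine
  - fibromyalgia
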