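# Default CTCAE toxicity-indicator rules — an editable, synthetic reconstruction.
#
# Each block defines one CTCAE category's detection logic across four evidence
# channels: laboratory indicators (absolute thresholds or baseline-relative
# ratios), indicator-drug ATC trigger sets (all codes of one set co-started
# within 3 days), case-insensitive whole-word keywords scanned over imaging
# reports, and ICD-10 admission diagnosis codes (main or secondary).
# Lab thresholds sit at CTCAE grade boundaries (creatinine >1.5x baseline
# ~ grade 2 acute kidney injury; bilirubin >3x ULN of 17 umol/L and
# ALT >5x ULN of 40 U/L ~ grade 3 hepatic toxicity).  The keyword channel is
# deliberately negation-blind.

acute_renal_failure:
  lab_rules:
    - {analyte: creatinine, unit: umol/L, comparator: ">", threshold: 1.5, baseline_relative: true}

hemorrhage:
  keyword_rules: [hemorrhage, haemorrhage, bleeding, bleed, hematoma]
  admission_codes: [R58, K92.2, I61.9, K62.5]

hepatic_toxicity:
  lab_rules:
    - {analyte: bilirubin, unit: umol/L, comparator: ">", threshold: 51.0, baseline_relative: false}
    - {analyte: alt, unit: U/L, comparator: ">", threshold: 200.0, baseline_relative: false}

icu_admission:
  icu_flag: true

invasive_aspergillosis:
  drug_rules: [[J02AC03], [J02AC05]]
  keyword_rules: [aspergillosis, aspergillus]
  admission_codes: [B44.0, B44.1, B44.7]

invasive_candidiasis:
  drug_rules: [[J02AX04], [J02AX06], [J02AC01]]
  admission_codes: [B37.7, B37.1]

pulmonary_toxicity:
  keyword_rules: [pneumonitis, ground-glass]
  admission_codes: [J70.2, J70.4, J84.9]

sepsis:
  drug_rules: [[J01DH02], [J01CR05, J01XA01]]
  admission_codes: [A41.9, A41.5, R65.2]

typhlitis:
  drug_rules: [[J01DE01, J01XD01]]
  admission_codes: [K52.9, K55.0]

venous_thrombosis:
  drug_rules: [[B01AB05], [B01AB04], [B01AF01], [B01AF02]]
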