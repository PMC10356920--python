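# Code sets for the dyslipidemia / statin / open-angle glaucoma study.
#
# ICD-10 diagnosis codes are dotless; a 3-character category matches all of
# its subcodes; "A-B" is an inclusive range compared at the endpoints'
# length.  Prescription codes are EphMRA-ATC; statin substance codes use the
# package's synthetic claims dialect (one disjoint code per substance).

dyslipidemia:
  system: ICD10
  codes: [E78]

outcome:
  diagnosis:
    system: ICD10
    codes: [H401, H406, H409]
  drug:
    system: ATC_EPHMRA
    codes: [S1E2]
  surgery:
    system: JP_PROCEDURE
    codes: [K268]

statins:
  rosuvastatin: C10A11
  atorvastatin: C10A12
  pitavastatin: C10A13
  pravastatin: C10A14
  simvastatin: C10A15
  fluvastatin: C10A16

covariates:
  - name: diabetes_mellitus
    kind: diagnosis
    system: ICD10
    codes: [E11, E14]
  - name: hypertension
    kind: diagnosis
    system: ICD10
    codes: [I10]
  - name: hypotension
    kind: diagnosis
    system: ICD10
    codes: [I95]
  - name: hyperuricemia_gout
    kind: diagnosis
    system: ICD10
    codes: [E790, M10]
  - name: arrhythmia_heart_failure
    kind: diagnosis
    system: ICD10
    codes: [I48, I49, I50]
  - name: ischemic_heart_disease
    kind: diagnosis
    system: ICD10
    codes: [I20-I25]
  - name: cerebrovascular_disease
    kind: diagnosis
    system: ICD10
    codes: [I60-I69]
  - name: transient_ischemic_attack
    kind: diagnosis
    system: ICD10
    codes: [G45]
  - name: migraine
    kind: diagnosis
    system: ICD10
    codes: [G439]
  - name: obstructive_sleep_apnea
    kind: diagnosis
    system: ICD10
    codes: [G473]
  - name: myopia
    kind: diagnosis
    system: ICD10
    codes: [H521]
  - name: infectious_inflammatory
    kind: diagnosis_composite
    system: ICD10
    groups:
      behcet_disease: [M352]
      congenital_rubella: [P350]
      cmv_retinitis: [B258, B259]
      herpetic_disease: [B00, B01, B02]
      hla_b27_related: [M02, M45, L405]
      juvenile_idiopathic_arthritis: [M080]
      lyme_disease: [A692]
      rheumatoid_arthritis: [M05, M06]
      sarcoidosis: [D86]
      syphilis: [A50-A53]
      systemic_lupus_erythematosus: [M32]
      toxocariasis: [B830]
      toxoplasmosis: [B58]
  - name: beta_blocker
    kind: medication
    system: ATC_EPHMRA
    codes: [C7]
  - name: steroid
    kind: medication
    system: ATC_EPHMRA
    codes: [H2, S1B, S3B, S3C]
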