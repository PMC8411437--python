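name: ADDI
version: '1.0'
categories:
- category_id: reproductive
  name: Reproductive
  max_points: 2
  item_ids: [sub_infertility, amenorrhea]
- category_id: renal_amyloidosis
  name: Renal/amyloidosis
  max_points: 6
  item_ids: [amyloidosis, proteinuria, renal_insufficiency]
- category_id: developmental
  name: Developmental
  max_points: 3
  item_ids: [growth_failure, puberty_delay]
- category_id: serosal
  name: Serosal
  max_points: 1
  item_ids: [serosal_scarring]
- category_id: neurological
  name: Neurological
  max_points: 6
  item_ids: [developmental_delay, cognitive_impairment, elevated_intracranial_pressure,
    cns_involvement]
- category_id: ears
  name: Ears
  max_points: 2
  item_ids: [hearing_loss]
- category_id: ocular
  name: Ocular
  max_points: 3
  item_ids: [ocular_involvement]
- category_id: musculoskeletal
  name: Musculoskeletal
  max_points: 4
  item_ids: [joint_restriction, bone_deformity, osteoporosis, musculoskeletal_pain]
items:
- item_id: sub_infertility
  name: Sub/infertility
  category_id: reproductive
  base_points: 2
  levels: []
  pediatric_only: false
  applicable_sex: any
  criterion: >-
    Failure to achieve clinical pregnancy after 12 or more months of regular
    unprotected intercourse, not explained by a disorder in the unaffected
    partner.
- item_id: amenorrhea
  name: Amenorrhea
  category_id: reproductive
  base_points: 1
  levels: []
  pediatric_only: false
  applicable_sex: female_relevant
  criterion: >-
    Primary: no menarche by age 16 or within 5 years of thelarche.
    Secondary: absence of menses for 6 or more consecutive months in a woman
    with previous cycles.
- item_id: amyloidosis
  name: Amyloidosis
  category_id: renal_amyloidosis
  base_points: 0
  levels:
  - label: limited
    points: 2
    criterion: Symptomatic, tissue- or SAP-scintigraphy-confirmed; one organ affected.
  - label: extensive
    points: 3
    criterion: Symptomatic, confirmed; more than one organ affected.
  pediatric_only: false
  applicable_sex: any
  criterion: Symptomatic amyloidosis confirmed by Congo red tissue staining or SAP scintigraphy.
- item_id: proteinuria
  name: Proteinuria
  category_id: renal_amyloidosis
  base_points: 1
  levels: []
  pediatric_only: false
  applicable_sex: any
  criterion: >-
    Persistent urinary protein-to-creatinine ratio above 20 mg/mmol (first
    morning void), daily protein excretion above 0.3 g/24 h, or urine
    albumin-to-creatinine ratio above 15 mg/mmol.
- item_id: renal_insufficiency
  name: Renal insufficiency
  category_id: renal_amyloidosis
  base_points: 0
  levels:
  - label: moderate
    points: 2
    criterion: GFR between 15 and 60 mL/min/1.73 m2.
  - label: severe
    points: 3
    criterion: GFR below 15 mL/min/1.73 m2, dialysis or transplantation.
  pediatric_only: false
  applicable_sex: any
  criterion: GFR below 60 mL/min/1.73 m2, dialysis or transplantation.
- item_id: growth_failure
  name: Growth failure
  category_id: developmental
  base_points: 2
  levels: []
  pediatric_only: false
  applicable_sex: any
  criterion: >-
    At least two of three features: height below 3rd percentile / -2 SD for
    age; 6-month growth velocity below 3rd percentile / -2 SD for age;
    crossing of at least two centile lines on the growth chart. Adults
    (over 18): pathological short stature.
- item_id: puberty_delay
  name: Puberty delay
  category_id: developmental
  base_points: 1
  levels: []
  pediatric_only: false
  applicable_sex: any
  criterion: >-
    Tanner stage below -2 SD or below the 3rd percentile for age, or any
    Tanner stage after pharmacological induction of puberty.
- item_id: serosal_scarring
  name: Serosal scarring
  category_id: serosal
  base_points: 1
  levels: []
  pediatric_only: false
  applicable_sex: any
  criterion: >-
    Symptomatic adhesions or fibrosis of pericardium, pleura, peritoneum or
    retroperitoneum, supported by imaging, endoscopy or surgery.
- item_id: developmental_delay
  name: Developmental delay
  category_id: neurological
  base_points: 2
  levels: []
  pediatric_only: true
  applicable_sex: any
  criterion: >-
    Failure to reach age-appropriate milestones (language/speech, motor,
    social/emotional, cognitive). Paediatric patients only.
- item_id: cognitive_impairment
  name: Cognitive impairment
  category_id: neurological
  base_points: 3
  levels: []
  pediatric_only: false
  applicable_sex: any
  criterion: >-
    Requirement of special education for cognitive impairment, or IQ below
    70 on age-appropriate neuropsychological assessment.
- item_id: elevated_intracranial_pressure
  name: Elevated intracranial pressure
  category_id: neurological
  base_points: 2
  levels: []
  pediatric_only: false
  applicable_sex: any
  criterion: >-
    Signs and/or symptoms of elevated intracranial pressure supported by an
    appropriate technique (funduscopy, neuroimaging, CSF pressure).
- item_id: cns_involvement
  name: Central nervous system involvement
  category_id: neurological
  base_points: 3
  levels: []
  pediatric_only: false
  applicable_sex: any
  criterion: >-
    Focal or diffuse deficits, seizures or spinal cord symptoms; excludes
    neuropsychiatric disorders unrelated to the disease.
- item_id: hearing_loss
  name: Hearing loss
  category_id: ears
  base_points: 0
  levels:
  - label: moderate
    points: 1
    criterion: Confirmed hearing impairment not requiring hearing aids or a cochlear implant.
  - label: severe
    points: 2
    criterion: Hearing impairment requiring hearing aids or a cochlear implant.
  pediatric_only: false
  applicable_sex: any
  criterion: >-
    Sensorineural hearing impairment of the better ear confirmed by
    audiometry or an age-appropriate technique, or requirement of hearing
    aids / cochlear implant.
- item_id: ocular_involvement
  name: Ocular involvement
  category_id: ocular
  base_points: 0
  levels:
  - label: mild
    points: 1
    criterion: Ocular damage without visual impairment.
  - label: moderate
    points: 2
    criterion: Ocular damage with visual impairment.
  - label: severe
    points: 3
    criterion: Legal blindness.
  pediatric_only: false
  applicable_sex: any
  criterion: >-
    Ocular damage of the better eye (e.g. optic nerve atrophy, elevated
    intraocular pressure, cataract) documented by an ophthalmologist.
- item_id: joint_restriction
  name: Joint restriction
  category_id: musculoskeletal
  base_points: 2
  levels: []
  pediatric_only: false
  applicable_sex: any
  criterion: >-
    Fixed limitation of the normal range of motion affecting function, with
    or without destructive arthropathy or avascular necrosis.
- item_id: bone_deformity
  name: Bone deformity
  category_id: musculoskeletal
  base_points: 2
  levels: []
  pediatric_only: false
  applicable_sex: any
  criterion: Bone deformation or overgrowth on clinical examination and/or imaging.
- item_id: osteoporosis
  name: Osteoporosis
  category_id: musculoskeletal
  base_points: 1
  levels: []
  pediatric_only: false
  applicable_sex: any
  criterion: >-
    Reduced bone mineral density together with vertebral collapse and/or
    pathological fracture confirmed by imaging; low bone density alone is
    insufficient.
- item_id: musculoskeletal_pain
  name: Musculoskeletal pain
  category_id: musculoskeletal
  base_points: 1
  levels: []
  pediatric_only: false
  applicable_sex: any
  criterion: Non-inflammatory musculoskeletal pain impairing activities of daily living.
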