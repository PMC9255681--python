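# Example ICPC -> chronic-condition group mapping: 43 groups, each a list of
# ICPC code prefixes (letter + two digits). Group names and the 33/43 split
# mirror the published grouping; the code content is an illustrative stand-in
# with the same file format as the authentic supplementary table.
anxiety_disorder: [P74]
dementia: [P70]
depression: [P76]
epilepsy: [N88]
parkinson_disease: [N87]
memory_concentration_problems: [P20]
vertigo_dizziness: [N17, H82]
hypertension: [K86, K87]
cardiac_arrhythmia: [K78, K79, K80]
coronary_heart_disease: [K74, K75, K76]
heart_failure: [K77]
orthostatic_hypotension: [K88]
stroke_tia: [K89, K90]
diabetes: [T90]
kidney_disease: [U99]
hearing_disorder: [H84, H85, H86]
visual_disorder: [F83, F92, F93, F94]
previous_injury: [A80, A81]
back_neck_disorder: [L01, L02, L03, L83, L84]
osteoarthritis: [L89, L90, L91]
osteoporosis: [L95]
rheumatoid_arthritis: [L88]
vitamin_deficiency: [T91]
fatigue_weakness: [A04]
urinary_incontinence: [U04]
copd: [R95]
asthma: [R96]
pneumonia: [R81]
malignancy: [A79]
thyroid_disorder: [T85, T86]
obesity: [T82]
anemia: [B80, B81, B82]
sleep_disorder: [P06]
substance_use_disorder: [P15, P16]
peripheral_neuropathy: [N94]
migraine: [N89, N90]
peripheral_vascular_disease: [K92]
venous_disease: [K94, K95]
gastrointestinal_disorder: [D84, D85, D86]
liver_disorder: [D97]
prostate_disorder: [Y85]
chronic_skin_ulcer: [S97]
foot_problems: [L17]
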