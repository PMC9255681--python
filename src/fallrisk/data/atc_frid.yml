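# Example ATC -> fall-risk-increasing-drug (FRID) group mapping: 33 groups,
# each a list of ATC code prefixes (any dispensed code starting with a prefix
# sets the group indicator). The group names and counts mirror the published
# grouping; the prefix content here is an illustrative, internally consistent
# stand-in — substitute the authentic supplementary table (same file format)
# for real-registry work. Prefixes are mutually non-nested so the synthetic
# generator can emit one code per group without cross-activating groups.
proton_pump_inhibitors: [A02BC]
opioids: [N02A]
antihyperglycemic_drugs: [A10]
antidepressant_drugs: [N06A]
antiepileptic_drugs: [N03A]
antiparkinson_drugs: [N04]
urinary_incontinence_drugs: [G04BD]
nsaids: [M01A]
antipsychotics: [N05A]
anxiolytics: [N05B]
hypnotics_sedatives: [N05C]
thiazide_diuretics: [C03A]
loop_diuretics: [C03C]
potassium_sparing_diuretics: [C03D]
beta_blockers: [C07]
calcium_channel_blockers: [C08]
ace_inhibitors: [C09A]
angiotensin_ii_antagonists: [C09C]
nitrates: [C01DA]
cardiac_glycosides: [C01AA]
antiarrhythmics: [C01B]
alpha_blockers: [C02CA]
statins: [C10AA]
antithrombotics: [B01A]
antihistamines: [R06A]
antivertigo_drugs: [N07CA]
muscle_relaxants: [M03]
antimigraine_drugs: [N02C]
systemic_corticosteroids: [H02AB]
bisphosphonates: [M05BA]
glaucoma_eye_drops: [S01E]
laxatives: [A06A]
anticholinergic_inhalants: [R03BB]
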