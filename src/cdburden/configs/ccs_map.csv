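code,category
BG.RESP,respiratory_infections
BG.URO,urogenital_disorders
BG.MSK,musculoskeletal_disorders
BG.SKIN,skin_conditions
BG.NEURO,neurological_disorders
BG.PSY,psychiatric_mental_disorders
BG.GEN,general_exam
COND.OSTEOPOROSIS,musculoskeletal_disorders
COND.MUSCLE_WEAKNESS,musculoskeletal_disorders
COND.CARDIOVASCULAR_DISEASE,cardiovascular_disease
COND.HYPERTENSION,hypertension
COND.DIABETES,metabolic_disorders
COND.DYSLIPIDEMIA,metabolic_disorders
COND.OBESITY,metabolic_disorders
COND.MENSTRUAL_ABNORMALITY,endocrine_disorders
COND.DEPRESSION,psychiatric_mental_disorders
COND.ANXIETY,psychiatric_mental_disorders
COND.INFECTIONS,respiratory_infections
COND.ABNORMAL_WEIGHT_GAIN,metabolic_disorders
PIT.NEO,endocrine_disorders
PIT.HYPER,endocrine_disorders
PIT.ANT.OTH,endocrine_disorders
PIT.HYPOTHAL,endocrine_disorders
PIT.DIENCEPH,endocrine_disorders
255.0,endocrine_disorders
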