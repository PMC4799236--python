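# Comorbidity / complication definitions for the incidence analysis.
# Code sets are symbolic placeholders matching the synthetic generator's
# output; deployments substitute real diagnosis-code sets. `population`
# restricts the risk set (all / adults / children_only / females).
- name: osteoporosis
  codes: ["COND.OSTEOPOROSIS"]
  population: all
  category: musculoskeletal
- name: muscle_weakness
  codes: ["COND.MUSCLE_WEAKNESS"]
  population: all
  category: musculoskeletal
- name: cardiovascular_disease
  codes: ["COND.CARDIOVASCULAR_DISEASE"]
  population: all
  category: cardiovascular
- name: hypertension
  codes: ["COND.HYPERTENSION"]
  population: all
  category: cardiovascular
- name: diabetes
  codes: ["COND.DIABETES"]
  population: all
  category: endocrine_metabolic
- name: dyslipidemia
  codes: ["COND.DYSLIPIDEMIA"]
  population: all
  category: endocrine_metabolic
- name: obesity
  codes: ["COND.OBESITY"]
  population: all
  category: endocrine_metabolic
- name: menstrual_abnormality
  codes: ["COND.MENSTRUAL_ABNORMALITY"]
  population: females
  category: endocrine_metabolic
- name: depression
  codes: ["COND.DEPRESSION"]
  population: all
  category: mental_health
- name: anxiety
  codes: ["COND.ANXIETY"]
  population: all
  category: mental_health
- name: infections
  codes: ["COND.INFECTIONS"]
  population: all
  category: other
- name: abnormal_weight_gain
  codes: ["COND.ABNORMAL_WEIGHT_GAIN"]
  population: children_only
  category: pediatric
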