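# Case-finding algorithm configuration.
#
# The code values below are documented symbolic placeholders used by the
# synthetic-data generator and the test suite. A production deployment
# overrides them with the licensed ICD-9-CM / CPT-4 / HCPCS code lists for
# the eight pituitary condition/procedure rule sets. The Cushing's syndrome
# diagnosis code 255.0 is the one real literal the algorithm hinges on.
cs_codes: ["255.0"]
pituitary_sets:
  pituitary_neoplasm: ["PIT.NEO"]
  hyperfunction: ["PIT.HYPER"]
  other_anterior_pituitary_disorder: ["PIT.ANT.OTH"]
  hypothalamic_control_anterior_pituitary: ["PIT.HYPOTHAL"]
  diencephalohypophyseal_syndromes: ["PIT.DIENCEPH"]
  hypophysectomy: ["PROC.HYPOPHYSECT"]
  stereotactic_radiosurgery: ["PROC.SRS"]
  bipss: ["PROC.BIPSS"]
# Place-of-service codes identifying laboratories / diagnostic testing
# centers; CS and pituitary codes on such claims are not examined for
# selection (they may reflect rule-out testing).
lab_place_of_service: ["81"]
study_start: 2006-07-01
study_end: 2012-06-30
id_start: 2007-01-01
id_end: 2011-12-31
pre_days: 183
post_min_days: 183
match_ratio: 3
enrollment_gap_days: 0
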