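# Instrument registry: native scale, admissible range, and direction for every
# score column the pipeline knows about.  scale_kind is one of raw / ACSS / T /
# seconds.  integer: true means only whole-number values pass validation.
instruments:
  - {name: rcft_copy,   scale_kind: raw,     min: 0, max: 36,  higher_is_better: true,  integer: false}
  - {name: rcft_yn,     scale_kind: raw,     min: 0, max: 24,  higher_is_better: true,  integer: true}
  - {name: rcft_fcr,    scale_kind: raw,     min: 0, max: 24,  higher_is_better: true,  integer: true}
  - {name: tomm1,       scale_kind: raw,     min: 0, max: 50,  higher_is_better: true,  integer: true}
  - {name: wct_acc,     scale_kind: raw,     min: 0, max: 50,  higher_is_better: true,  integer: true}
  - {name: wct_t2c_s,   scale_kind: seconds, min: 1, max: 1200, higher_is_better: false, integer: false}
  - {name: cim,         scale_kind: raw,     min: 0, max: 12,  higher_is_better: true,  integer: true}
  - {name: ds_acss,     scale_kind: ACSS,    min: 1, max: 19,  higher_is_better: true,  integer: true}
  - {name: hvlt_fcr,    scale_kind: raw,     min: 0, max: 12,  higher_is_better: true,  integer: true}
  - {name: rey15_fr,    scale_kind: raw,     min: 0, max: 15,  higher_is_better: true,  integer: true}
  - {name: rey_wrt,     scale_kind: raw,     min: 0, max: 15,  higher_is_better: true,  integer: true}
  - {name: animals_t,   scale_kind: T,       min: 0, max: 120, higher_is_better: true,  integer: true}
  - {name: cd_acss,     scale_kind: ACSS,    min: 1, max: 19,  higher_is_better: true,  integer: true}
  - {name: tmta_t,      scale_kind: T,       min: 0, max: 120, higher_is_better: true,  integer: true}
  - {name: cpt_var_t,   scale_kind: T,       min: 0, max: 120, higher_is_better: false, integer: true}
  - {name: dkefs_word,  scale_kind: ACSS,    min: 0, max: 19,  higher_is_better: true,  integer: true}
  - {name: mr_acss,     scale_kind: ACSS,    min: 1, max: 19,  higher_is_better: true,  integer: true}
  - {name: cdt,         scale_kind: raw,     min: 0, max: 10,  higher_is_better: true,  integer: false}
  - {name: hvlt_dr_t,   scale_kind: T,       min: 0, max: 120, higher_is_better: true,  integer: true}
  - {name: hvlt_dr_raw, scale_kind: raw,     min: 0, max: 12,  higher_is_better: true,  integer: true}
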