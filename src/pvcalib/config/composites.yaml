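# Built-in composite definitions.
#
# Each component is a multi-cutoff ordinal recoding rule: ordered bands of
# closed integer intervals on the instrument's native scale (null = open end).
# Validity composites (EI-5) code 0 = passed the most liberal cutoff,
# 3 = failed the most conservative cutoff.  The ability composite (VPA-3)
# codes 0 (Impaired, about two SD below the normative mean) through
# 4 (Very Superior); 2 is the Average band.
#
# These tables are configuration, not code: edit a copy of this file and load
# it with pvcalib.recoding.load_composite_specs to audit or recalibrate
# cutoffs without touching the package.
composites:
  EI5_MEM:
    kind: validity
    band_thresholds: {pass_max: 1, borderline: [2, 3], fail_min: 4}
    completeness: require_all
    components:
      - instrument: cim
        bands:
          - {code: 0, min: 10, max: null}
          - {code: 1, min: 8, max: 9}
          - {code: 2, min: 7, max: 7}
          - {code: 3, min: null, max: 6}
      - instrument: ds_acss
        bands:
          - {code: 0, min: 7, max: null}
          - {code: 1, min: 5, max: 6}
          - {code: 2, min: 3, max: 4}
          - {code: 3, min: null, max: 2}
      - instrument: hvlt_fcr
        bands:
          - {code: 0, min: 12, max: null}
          - {code: 1, min: 11, max: 11}
          - {code: 2, min: 9, max: 10}
          - {code: 3, min: null, max: 8}
      - instrument: rey15_fr
        bands:
          - {code: 0, min: 12, max: null}
          - {code: 1, min: 7, max: 11}
          - {code: 2, min: 5, max: 6}
          - {code: 3, min: null, max: 4}
      - instrument: rey_wrt
        bands:
          - {code: 0, min: 7, max: null}
          - {code: 1, min: 5, max: 6}
          - {code: 2, min: 4, max: 4}
          - {code: 3, min: null, max: 3}
  EI5_PSP:
    kind: validity
    band_thresholds: {pass_max: 1, borderline: [2, 3], fail_min: 4}
    completeness: require_all
    components:
      - instrument: animals_t
        bands:
          - {code: 0, min: 32, max: null}
          - {code: 1, min: 26, max: 31}
          - {code: 2, min: 24, max: 25}
          - {code: 3, min: null, max: 23}
      # The published coding-subtest row is taken literally: code 0 requires
      # ACSS >= 6, code 1 is exactly 5.
      - instrument: cd_acss
        bands:
          - {code: 0, min: 6, max: null}
          - {code: 1, min: 5, max: 5}
          - {code: 2, min: 4, max: 4}
          - {code: 3, min: null, max: 3}
      - instrument: tmta_t
        bands:
          - {code: 0, min: 34, max: null}
          - {code: 1, min: 23, max: 33}
          - {code: 2, min: 20, max: 22}
          - {code: 3, min: null, max: 19}
      # CPT-3 Variability: higher T = worse performance, so bands run upward.
      - instrument: cpt_var_t
        bands:
          - {code: 0, min: null, max: 64}
          - {code: 1, min: 65, max: 74}
          - {code: 2, min: 75, max: 79}
          - {code: 3, min: 80, max: null}
      # The published table leaves scaled score 0 unmapped (lowest band is
      # exactly 1); scores below the lowest band extrapolate to the maximum
      # code with a warning.
      - instrument: dkefs_word
        below_floor_code: 3
        bands:
          - {code: 0, min: 6, max: null}
          - {code: 1, min: 4, max: 5}
          - {code: 2, min: 2, max: 3}
          - {code: 3, min: 1, max: 1}
  VPA3:
    kind: ability
    band_thresholds: null
    completeness: require_all
    components:
      - instrument: cd_acss
        bands:
          - {code: 0, min: null, max: 4}
          - {code: 1, min: 5, max: 7}
          - {code: 2, min: 8, max: 12}
          - {code: 3, min: 13, max: 15}
          - {code: 4, min: 16, max: null}
      - instrument: mr_acss
        bands:
          - {code: 0, min: null, max: 4}
          - {code: 1, min: 5, max: 7}
          - {code: 2, min: 8, max: 12}
          - {code: 3, min: 13, max: 15}
          - {code: 4, min: 16, max: null}
      - instrument: tmta_t
        bands:
          - {code: 0, min: null, max: 30}
          - {code: 1, min: 31, max: 43}
          - {code: 2, min: 44, max: 56}
          - {code: 3, min: 57, max: 69}
          - {code: 4, min: 70, max: null}
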