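# Example free-standing PVT decision rules.
#
# tomm1_fail_max is deliberately site-configurable: laboratories differ in the
# Trial-1 cutoff they adopt, and no single value is endorsed here.  The value
# below is an illustrative placeholder used by the bundled presets and
# examples; replace it with your laboratory's adopted cutoff.
tomm1_fail_max: 43
wct_acc_fail_max: 47
wct_t2c_fail_min_s: 156
rcft_cutoffs: [15, 16, 17, 18]
chance_threshold: 12
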