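# Representative organ tolerance presets for gEUD-based NTCP
# (logistic dose-response on EUD).  Columns:
#   organ  a  td50_gy  gamma50
# These are commonly cited literature-derived defaults intended as a
# starting point only; users should verify and substitute values
# appropriate to their own clinical context before use.
brainstem      7    65.0   3.0
spinal_cord    20   66.5   4.0
larynx         8    70.0   4.0
lung           1    24.5   2.0
heart          3    50.0   3.0
parotid        1    46.0   4.0
cochlea        8    55.0   3.0
esophagus      19   68.0   4.0
rectum         12   80.0   4.0
bladder        2    80.0   4.0
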