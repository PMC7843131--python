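off_axis_mm,contrast
22.16,4.50
29.96,6.52
38.48,6.06
45.04,3.62
53.90,3.27
60.46,2.101
66.84,1.88
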