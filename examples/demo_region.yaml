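# Default region (300x300 km, 3 urban centers, 400 block groups,
# 12 ICU facilities) with a strong disparity gradient.
disparity_knob: 0.8
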