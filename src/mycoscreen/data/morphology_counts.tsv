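morphology	n	positives
polycentric	26	12
monocentric	120	11
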