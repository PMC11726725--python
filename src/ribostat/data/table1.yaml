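# Spreadsheet scenario: well-mixed chemistry with jump noise on [A].
dt: 0.001
k1: 1.0
k2: 1.0
k3: 1.0
k4: 1.0
cX: 100.0
cY: 24.45
cA: 7.0
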