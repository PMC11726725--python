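# Self-replication scenario: same chemistry, agent copies itself (2A -> 3A).
A0: 7.0
cX: 100.0
cY: 24.45
kRR: 1.0
dR: 0.01
k1: 1.0
k2: 1.0
k3: 1.0
k4: 1.0
dt: 0.001
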