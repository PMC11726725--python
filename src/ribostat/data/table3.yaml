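# Spatial multi-agent scenario (replicases, parasites, inhibitor pairs).
# Dprime is the complexes' diffusion constant; delta the offspring mutation
# probability; K_repl the global replication constant.
sizeX: 1050.0
sizeY: 675.0
init_R: 2250
init_P: 112
agent_size: 3.0
Nmax: 4
d: 0.1
aR: 0.8
aP: 0.8
lP: 0.2
D: 400.0
Dprime: 400.0
delta: 0.1
dt: 1.0
K_repl: 1.0
k1: 10.0
k2: 5.0
k3: 10.0
k4: 5.0
n_inhibitors: 0
n_anti_inhibitors: 0
target_mode: only_P
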