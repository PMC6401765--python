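# Symmetric diblock (500 flexible + 500 semi-flexible beads) confined in the
# d_p = 6.9, S_p = 12 array (long-running benchmark).
# Expected occupation numbers: whole chain ~ 26.7, semi-flexible block ~ 21.5,
# flexible block ~ 8.05.  The structure factor develops a hump at
# q ~ 2*pi/S_p ~ 0.524.
N: 1000
blocks: diblock
b: 20.0
S_p: 12.0
d_p: 6.9
n_y: 8
n_z: 8
dt: 0.005
T: 1.0
thermostat: nose_hoover
gamma_or_tau: 0.1
n_equil: 10000000
n_prod: 40000000
sample_interval: 10000
seed: 3
replicas: 3
orientation: parallel
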