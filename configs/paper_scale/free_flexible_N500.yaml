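# Free flexible homopolymer, N = 500 (long-running benchmark).
# Expected equilibrium axial span ~ 38.08 sigma.
N: 500
blocks: flexible
b: 0.0
dt: 0.005
T: 1.0
thermostat: nose_hoover
gamma_or_tau: 0.1
n_equil: 10000000
n_prod: 40000000
sample_interval: 10000
seed: 1
replicas: 3
orientation: parallel
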