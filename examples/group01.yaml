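# Treatment group 1: 50 mW/cm2 for 600 s (30 J/cm2), [BPD]pre = 0.53 uM.
group: 1
fluence_rate: 50        # mW/cm2, in air
time: 600               # s
BPD: 0.53               # uM
fluence_J_cm2: 30       # cross-checked against rate x time
source: {diameter_mm: 10}
grid: {n: 100, voxel_mm: 0.5}
optics: {mu_a: 0.69, mu_s_prime: 11, g: 0.9, n: 1.4}
pk: {g_supply: 1.7, delta: 33, beta: 11.9, sigma: 1.8e-5, xi: 0.055, O2_uM: 40}
mc: {n_photons: 2000000, seed: 0, weight_threshold: 1.0e-4, roulette: true}
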