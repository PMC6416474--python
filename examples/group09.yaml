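# Treatment group 9: 75 mW/cm2 for 2000 s (150 J/cm2), [BPD]pre = 0.84 uM.
# Defaults (10-mm beam, 100^3 x 0.5 mm grid, tumor optics, BPD kinetics) apply.
group: 9
fluence_rate: 75
time: 2000
BPD: 0.84
fluence_J_cm2: 150
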