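# Treatment group 14: 150 mW/cm2 for 2333 s (350 J/cm2), [BPD]pre = 0.81 uM.
group: 14
fluence_rate: 150
time: 2333
BPD: 0.81
fluence_J_cm2: 350
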