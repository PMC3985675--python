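# four codesigned transition seeds, weight 5.5, gapless length 64
# alignment model (transversion, transition, match) = 0.12,0.18,0.7
# joint sensitivity 0.999969
11T101001
1T1T0T110
1101100TTT
T1TT0T0T011
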