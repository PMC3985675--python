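# four codesigned transition seeds, weight 5.5, gapless length 64
# alignment model (transversion, transition, match) = 0.15,0.15,0.7
# joint sensitivity 0.999926
11010T011
0111001T1
1101100T01
1T0T0010T11
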