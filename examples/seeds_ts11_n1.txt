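# single transition seed, weight 5.5, designed for gapless length 64
# alignment model (transversion, transition, match) = 0.15,0.15,0.7
# sensitivity 0.994044
10010T0111
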