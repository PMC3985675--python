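# single transition seed, weight 5.5, designed for gapless length 64
# alignment model (transversion, transition, match) = 0.12,0.18,0.7
# sensitivity 0.997011
1T0T0T10TT1
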