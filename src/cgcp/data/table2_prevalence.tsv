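population	prevalence
JPT	0.0034
CHB	0.0047
YRI	0.009
ASW	0.011
GBR	0.015
IBS	0.015
ITU	0.023
CEU	0.025
TSI	0.034
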