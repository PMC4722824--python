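>t1
GGCTTTCGCCAGATAAAGGTATTTAAT
>t2
AGCTATCGCCAGATAAAGGTATTTAAT
>t3
AGCTTTCGCCAGATGAAGGTATTTAAT
>t4
AGTTATCGCCAGATGAAGGTATTTAAT
>t5
AGTCTTCGCCAGATGAAGGTATTTAAT
>t6
AGTCTTCGCCAGATGAAGGTATTTAAT
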