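>t1
GCGTTCACCAGGCTAGGCAAGGGTAAGGGTGCTAAATGCA
>t2
GCGATCACCAGCCTAGGCAAGGGTCAGGGTCCTAAATGCA
>t3
GCGTTCACCAGCCTAGGAAAGGGTCCGGGTCCTAAATGCA
>t4
GCGTTCACCAGGCTAGGCAAGGGTAAGGGTGCTAAATGCA
>t5
TCGTTCACCAGGCTAGGCAAGGGTAAGGGTCCTAAATGCA
>t6
GCGATCACCAGGCTAGGCAAGGGTAAGGGTCCTAAATGCA
>t7
GCGTTCACCAGGCTAGGCAAGGGTCCGGGTCCTAAATGCA
>t8
GCGATCACCAGGCTAGGCAAGGGTAAGGGTCCTAAATGCA
>t9
GCGATCACCAGCCTAGGCAAGGGTACGGGTCCTAAATGCA
>t10
GCGTTCACCAGCCTAGGCAAGGGTAAGGGTCCTAAATGCA
>t11
GCGATCACCAGCCTAGGCAAGGGTACGGGTCCTAAATGCA
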