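>t1
CAGGTAAAGACTACTGTCACGTTTTACGGATGAGGAAGGTGTTTGAACACAATG
>t2
CAGGTAAAGACAACTGTCACGTTTTACGGATGAGGAAATTGTTTCAACACAATG
>t3
CAGGTAAAGATTACTGTCACGTTATACGGATGAGGAAAGTGTTTCAACACAATG
>t4
CATGTAAAGACAACTGTCACGTTTTACGGATGAGGAAATTGTTTCAACACAATG
>t5
CATGTAAAGATAACTGTCACGTTTTACGGATGAGGAAATTGTTTCAACACAATG
>t6
CAGGTAAAGACTACTGTCACGTTTTACGGATGAGGAAAGTGTTTCAACACAATG
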