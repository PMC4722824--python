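>t1
ATGACCAGGCCATATCTAGCTGTTGTGGGTTCCAGATT
>t2
ATGACGAGGCCCTATCTAGCTGTTATGGGTTCTAGATT
>t3
ATGACGAGCCCATATCGAGTTGTTACGGGTTCCAGATT
>t4
ATGACGAGGCCATATCGAGCTGTTGTGGGTTCTAGATT
>t5
ATGACGAGGCCCTATCTAGTTGTTACTGGTTCTAGATT
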