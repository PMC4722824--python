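>t1
CACCCATTTATTGGCACGCGATCTCCCTTCCGATGACAC
>t2
CACCCATTTATTGGCACGCGGTCTCCCTTCCGATGACTC
>t3
CACCCATTTATTGGCACGCGGTCTCCCTTCCGATGACTC
>t4
CACCCATTTATTGGCACGCGGTCTCCCATCCGATGACTC
>t5
CACCCATTTATTGGCACGCGATCTCCCTTCCGATGACTC
>t6
CACCCATTTATTGGCACGCGGTCTCCCATCCGATGACAC
>t7
CACCCATTTATTGGCACGCGGTCTCCCATCCGATGACTC
>t8
CACCCATTTATTGGCACGCGGTCTCCCATACGATGACTC
>t9
CACCCATTTATTGGCACGCGGTCTCCCATCCGATGACAC
>t10
CACCCATTTATTGGCACGCGGTCTCCCATCCGATGACTC
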