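>T2L01
CCCACTCCCAGCCCCGCAGGGGGCCCTGACCCCACCTCACCCAGCTCGGACTCTGGCACGGCCCAGGCTGCCCCGCCACTGCCTCCACCCCCCGAGTCGGG
>T2L02
CACTCCCAGCCCCGCAGGGGGCCCTGACCCCACCTCACCGGCAGAGGGGGTCTCCCAACCTGCCCCGGCGCGCGGGGATTTCGCCTACGCCGCCCCGGCTC
>T2L03
CGCCCCCCACTGGCACCGCTGCTGCCCCTGCCCCCACTCCCAGCCCCGCAGGGGGCCCTGACCCCACCTCACCGGCAGAGGGGGGCTCCCAACCTGCCCCG
>T2L04
CGCTGCTGCCCCTGCCCCCACTCCCAGCCCCGCAGGGGGCCCTGACCCCACCTCACCGGCAGAGGGGGTCTCCCAACCTGCCCCGGCGCGCGGGGATTTCG
>T2L05
CCTGCCCCCACTCCCAGCCCCGCAGGGGGCCCTGACCCCACCTCACCGGCAGAGGGGGTCTCCCAACCTGCCCCGGCGCGCGGGGATTTCGCCTACGCCGC
>T2L06
CACCGCTGCTGCCCCTGCCCCCACTCCCAGCCCCCCAGGGGGCCCTGACCCCACCTCACCGGCAGAGGGGGCCTCCCAACCTGCCCCGGCGCGCGGGGATT
>T2L07
TGGCACCGCTTCTGCCCCTGCCCCCACTCCCAGCCCCGCAGGGGGCCCTGACCCCACCTCACCCAGCTCGGACTCTGGCACGGCCCAGGCTGCCCCGCCAC
>T2L08
CCTGCCCCCACTCCCAGCCCCGCAGGGGGCCCTGACCCCACCTCACCGGCAGAGGGGGTCTCCCAACCTGCCCCGGCGCGCGGGGATTTCGCCTACGCCGC
>T2L09
CGCTGCTGCCCCTGCCCCCACTCCCAGCCCCGCAGGGGGCCCTGACCCCACCTCACTTGCAGAGGGGGTCTCCCAACCTGCCCCGGCGCGCGAGAGATCGG
>T2L10
CCTCTCCCTGTACCGCCCCCCACTGGCACCGCTGCTGCCCCTGCCCCCACTCCCAGCCCCGCAGGGGGCCCTGACCCCACCTCACCGGCAGAGGGGGTCTC
>T2L11
CCCAGCCCCGCAGGGGGCCCTGACCCCACCTCACCCAGCTCGGACTCTGGCACGGCCCAGGCTGCCCCGCCACTGCCTCCACCCCCCGAGTCGGGGCCTGG
>T2L12
CCTGCCCCCACTCCCAGCCCCGCAGGGGGCCCTGACCCCACCTCACCGGCAGAGGGGGACTCCCAACCTGCCCCGGCGCGCGGGGATTTCGCCTACGCCGC
>T2L13
CCCCACTCCCAGCCCCGCAGGGGGCCCTGACCCCACCTCACCGGCAGAGGGGGTCTCCCAACCTGCCCCGGCGCGCGGGGATTTCGCCTACGCCGCCCCGG
>T2L14
CTCCCAGCCCCGCAGGGGGCCCTGACCCCACCTCACCGGCAGAGGGGGTCTCCCAACCTGCCCCGGCGCGCGGGGATTTCGCCTACGCCGCCCCGGCTCCT
>T2L15
CCACTGCCAGCCCCGCAGGGGGCCCTGACCCCACCTCACCCAGCTCGGACTCTGGCACGGCCCAGGCTGCCCCGCCACTGCCTCCACCCCCCGAGTCGGGG
>T2L16
CACTCCCAGCCCCGCAGGGGGCCCTGACCCCACCTCACCGGCAGAGGGGGTCTCCCAACCTGCCCCGGCGCGCGGGGGTTTCGCCTACGCCGCCCCGGCTC
>T2L17
CCCCTGCCCCCACTCCCAGCCCCGCAGGGGGCCCTGACCCCACCTCACCGGCAGAGGGGGCCTCCCAACCCGCCCCCGCGCGCGGGGGCTGCGCCTACGCC
>T2L18
CCCACTCCCAGCCCCGCAGGGGGCCCTGACCCCACCTCACCGGCAGAGGGGGTCTGCCAACCTGCCCCGGCGCGCGGGGATTTCGCCTACGCCGCCCCGGC
>T2L19
CCGCTGCTGCCCCTGCCCCCACTCCCAGCCCCGCAGGGGGCCCTGACCCCACCTCACCCAGCTCGGACTCTGGCACGGCCCAGGCTGCCCCGCCACTGCCC
>T2L20
CACCGCTGCTGCCCCTGCCCCCACTCCCAGCCCCGCAGGGGGCCCTGACCCCACCTCACCGGCAGTGGGGGTCTCCCAACCTGCCCCGGCGCGCGGGGATT
>T2L21
GGCACCGCTGCTGCCCCTGCCCCCACTCCCAGCCCCGCAGGGGGCCCTGACCCCACCTCACCGGCAGAGGGGGTCTCCCAACCTGCCCCGGCGCGCGGGGG
>T2L22
CCAGCCCCGCAGGGGGCCCTGACCCCACCTCACCGGCAGAGGGGGTCTCCCAACCTGCCCCGGCGCGCGGGGATTTCGCCTACGCCGCCCCGGCTCCTCCC
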