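>1
TACTTTGACGTCTGGGGCGCAGGGACCACGGTCACCGTCTCCTCA
>2
TACTTTGACTACTGGGGCCAAGGCACCACTCTCACAGTCTCCTCA
>3
TGGTTTGCTTACTGGGGCCAAGGGACTCTGGTCACTGTCTCTGCA
>4
TACTATGCTATGGACTACTGGGGTCAAGGAACCTCAGTCACCGTCTCCTCA
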