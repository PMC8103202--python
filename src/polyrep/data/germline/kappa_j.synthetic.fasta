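>1
TGGACGTTCGGAGGGGGGACCAAGCTGGAAATAAAA
>2
TACACGTTCGGCGGAGGGACCAAGCTGGAGCTGAAA
>3
ATCACATTCGGTGCTGGGACCAAGCTGGAGCTGAAA
>4
TTCACGTTCGGCTCGGGGACAAAGTTGGAAATAAAA
>5
CTCACGTTCGGTGGAGGCACCAAGCTGGAAATCAAA
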