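>1-1
TCTACTATGGTTAC
>2-12
TTGTATCCCGGTTG
>2-4
AGGATAGTACCAGC
>3-3
GCAAGGCTGGAACG
>4-1
CCTCGACTAAGCAT
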