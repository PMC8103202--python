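>10-94
GCCGTCATGATGACCCAAAGACACAGCGGCCTGGTCGTGAGCGCCTGCGAGAAGGTGTCCATCAGATGCAACAGTAGGCAGAGCCTGCTGACTAGCTGCTGGTACCCGCAGATGCCCGGCCAGATCCCCAAGCTGCTGATCTACAGCGCCAGCTCCAGAGAGAACGGCGAGCGCGACAGATTCACCGGCAGCGGCAGCGGCGCCGACTTCACACTGCCCATCAGCAACGAGCGGGCCGAGGAGCTGTCCGTGTACTATTGTCAGCAGTACAGCAAGCTGCCC
>12-44
GCCATCGTGATCACCCAGAGGACCAGAAGGCTTGCCGTGAGCGCCGGCGGGAAGGTGACCATGAGCTGTAAGAGCAGCCAGACGTTGTTGAACAGAGGCTGGCACCAGCAGCAGCGCGGCCAGAGCTCCAAGCTGCTGGTCTACTGTGCCAGCACCAGAGTGAGCGGCGCGCCCGACAGACACTCCGGCATCTGGAGCGGCACCGACTTCACCGTGACCATAACCAACGATGAGGCCAAGGACATGGCCGTGTACTACTGTCAGCACCACTACGGCACCCCC
>12-46
AACATCGGGAGGCGCCAGAGCGCCTGGAGCCTGGCCGTGAGCTCCGACGAGAAGGTGAGCATGAGCTATAAGAGCATCCAGAGCCTGCGGAAAAGCGGCTGGTACCAGCAGAAGCCCGGCCAGAGCTCCAAGCTGCGGATCTACTGGGTCATCACCAAAGGGAGTTGGGTGCGCGACAGTTTCACGGGCAGCGGCACCGCCACTGACTTCACCCTGCCCATCAGCATCGTGCATGCGGAGGACGTGGCCGTGTACTACTGTCAGCACTTCTACGGCACCCCC
>13-85
GCCATCGGGATGACCCAGATCCCAAGCAGCCTGAACTTGAGCGCCAGCGATACGGAGTCCACGAGCTGTAAGAGCGGCCAGATCCCGCTGAACAGCGGCTGGTATCAGCAGAATCCCGGCCAGAGGCCCAAGCTGCCGATCTACTGGGCAAGCACCATAGAGAGGGGCGCGCCCGACAGAGGCACCGTCAGCGGCAGCCGCACCTTCTACACCCTGATCATCAGCAGCGTGCAGGTCGACGACTTGGCAGTGTACCACTGTCAGCAGTACTGGGGCACCCCC
>3-10
GATATCATGATGACCCAGGGCCCCAGCGGCGGGGCCGCGCGCGCCGGGGAGAGCGTGACCAGGTGCTGTAAGAGCAGCCGGCGCCTGCTGAACAGCGGGTGGTTCGAGCAGAAGCCCGGCCAGAGCCCCAAGCTGCTGATGTACTGGGCCAGGACCACAGAGCGCGGTGTGCCCGACAGATTCACCGCCAGCAGCAGTGGCACCGACTGCACCCTGACAACCAGCAGCGTGCTGGCTTGCGACCTGGCCGTGTACTACTGTCAGCAGAACAACGAGGACCCC
>3-4
GACATCGTGATGACCCCGAGCCCCAGCAGCCTGGCCGAGGGCGCCGGCGAGCAGGCGACCAAGAGCTGTAAGAGCAGCCTTAGCCTGCTGGACAGTGGCAGGTACCACCGGAAACCGGGCCAGAGCCCCAAGCTGATGATCTACTGGGCCAGCACCAGAAAGAACGTCGTGCGGAACACGTTCACCGGCAGCGAAAGCGGCACCAACTTAACCCTGACCATAAGCAGCGTAAAGGCCGAGGACCTAGCCATGTACGACTGTCAGCAGAGCAAGGAGTTCCCC
>4-74
GATACCGTGATGACGCAGAGCCCCATGCGCCTGGCTATCAGCGGCCGTGAGAAGCTGACCATAAGCATTAAGAGGAGCCAGAGCCTGCCGCACAGTGATGGGTACCAGCAGAAGCCCGGCCAGAGCACCAAGCTTCTGATCTACTGGGCCAGCAGCAGACAGAGCGGCGTGCTCGACAGATTCGCCGCCATCGGCAGCCGCTTCGACTTCACCCTGACCATCAGAACCGTGCTGTCCGAGGACCTGTCCGTGTACTACTGTCAGCAGTACCACAGCGACCCC
>4-91
GACATTGTGATGACCCAGATCCGCAGCCACCTTACCAGGAGCGCCGACGAGAAGGTGACCATGAGCTGTAAGAGAAGCCAGAGCCGCCTGAACTACCGCTGGTTCCAGAAGAAGCTCGGCAAGAGCCCCAAGCTGCGGATCTACTGGGCTAGAAACAGAGAGCGCGGCCTGCCCGACATCTTCACAGGCAGCGGGAGTGGCATCGATTTCACCCCGACCATCAGCAGCGTACTGGCCGAGCACCTGGCCGTGCACTACTGTCAGCACGGCAGCAGCCTGCTG
>5-45
GACCCATTGATGGCCCAGAGCGCCAACATCCTGGCCGCGGGCGCCGGCGAGAAGGTGTCCATGCGCTGTACGATCACCCATAGCCTCCTTAACAGCGGCTGGTGCCAGCAGAAACCCGCACAGAGCCCCCAGCTGGTGATCTACTGGGTCCGCACCAGAGAGGGCGGCCTGCCCGACAGAATTGCCGGCCGCGGCAGAGGCACGGACTTGGCCCTGACTATCAGCAGCGTGCAGACCGAGGACCTGGCCGTGTACTACTGTCAGCAGAGCAACAGCTGGCCC
>6-20
GTCGTCGTTATGATCCAGAGACCCAGCATCTTCGCGTTGAGCGCAGGCGAGAAGCTGCGCATGAGCTGTAAGAGCAGCCAGGGGTTGCTGAACAGCGGCTGGTACCAGCGGAAGCATGGCCTGAGCCCCAAGCTGCTGAGTTACTGGGTAATCACCGGAGGGAGCGGCGTGCTCAACAGATTCACCGGCAGCGGCAGGGGCACCGATGTCACCCTGAACATCAGCGGCGTGCAGGCCGAGGACCTGGCCGTGGACTACTGTGGCCAGAGCTACAGCTACCCC
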