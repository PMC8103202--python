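>1-22
GAGGTGCAGCTGCCGCAGAGAGGCACCGAGCTGGTCCAGCCCGGCTCAAACGTGAATCTGAGCTGGAAGGCCAACGGCTTGACGTTCACCAACTACTGGATGAACTGGGTGAAGCCGACACCCGGCCAGGGCCTGGAGTGTACAGGCGTGATCCTGCCCGTCAGCGGTAGCAGCAACTACAACGAGAAGTTCAAGGGCAAGGCGACCCTGACCACCGAAACGTGCTGCAGCACCGCCTTCATGCAGCAGAGCGACCTGACCAGCGATGTTAGCACCGTGTACTACTGTGTCAGA
>1-26
GAGGTGCAGCTGGAGCTGAGCGGCGCCGAGTCCGTGAAGCCCGGGGCCAACGTGAAGCTGAGCTGTAGAGCGAGCGGCTACACCTTCACCAGCTACTGGAATATCTGGGTGAAGCATAGACCCGGCCAAGGGCTGGACTGGATCGGCGAGATCCTGCCCGGCAGCTGCAGCCCTGCCTACAACGCGCAGTTCAGGGGAAAGGTCACACTGACCGCCGACACCGGCAGCAGCTCCGCCCACATGCAGCTGAGCAGTCTCATAACCGAGGACAGCGCTATGTATCACTGTGCCCGA
>1-39
GAGATGCAGCTGCCGAAGAGCGGCGGCGAGCGGGTGAAGCCCGGCGCCAGCGTGAAGCTGAGCTGTAAGGCCAGCGGTAAAACCATCATCAGCTATAGGATCAACTGGGTGACTCAGAGACCCGGCAAGGGCCTTGAGTGGATCGGCGAGATCCTGCCCCGCAGCGACAGCACCTACTACAACGAGAAGATCAAGGGCATGCCCACCCTGCCCGCAGAAAGGGGGAGAAGCACCGCCAACATGCATCTGCCTAGCCTGCCTACCGAGGACAGGGCCTTGTACACCTGTACCAGA
>1-4
GAGGTGCAGCTGCAGCAGAGTGGCGCCAAGCTGGTGACACCCGGCGCAAGGGTGAGGCTGCGCTGTCAGGCCAGCGGCTACAGCTTCACCTGCTACTGGATCCGCAGGGTGAAGCAAAGACCCGGCCAGGGGCTGGAGTGGATGGGCGATGTCCTGCCCGACATCGGCCGCACCAACCACCATGAGACGATCAAGGGCAAGGCCACCCTGACTGCCGACAAGAGCAGCAGTACCGCTTACATGCTGCTTCACAGCCTCACCAGCGTGGACAGCCGCGTGTACTACTGTGCCAGA
>1-43
GAGGTGCAGCTGCAGCAGAGCACCGCCGGGCTGATGAGGCCCGGGGCCCGCGTGAAGCTGAGCTCTAAGGCCAGCGGATACAACCTCACCACCTACTCGATCAATTGGGTGAAGCAGAGACCCGGCCAGGGCCTGATGTGGATCGGCGAGATCGTGGCCGGCAGCCGCAGCACCAACTACAACGAGAAGTGCAAGGGCAAGCCGACCCTGACCGTCCACAAGAGCAGGAGCACCAGCCTCATCCATCCGAGAAGCCTGACGAGCGAGGACCGAACGGAGTATCACTGTGCAAGT
>1-7
GAGGTGCAGCGGCAGCAGAGCGGCGACGAGGTGGTGAATCCCGGCATCAACGTGACGCGGAGTTGTCAGGTCAGCGCCTACACCTTCACCAGCTACGGGATTAACTGGATGCAGAAGAGACCCGGCCAGCGCCTGCAGTGGATCGGCGAGATCCTGCCCGCCAGCGGCTGCAACAACTCCTACGGGAAGTTTACGGGCAAGGCCCTCCTGACCGCCGACAATCGCAGAAGCCCCGCCTACATGCAGCTAAGCTGCCTGACCAGCGTCGACAGCGCCGTGTACTACTGTACCAGC
>10-3
GAGGTGCAGCTGCAGCAGAGCGGCGCCGAGCTGGTGAAGCCCGGCGCCAGCGTCAAGCGGACCTGTAAGGCCAGCCGCTACAGCCTCACCATATTCTGGATCCCCTGCGAGAAGCAGAGATCCGGCCAGGGCCTGGAGGGGGTCTGCGGTGGCTTGCCAGGCAGCCGCACCACCAACTACAGCGAAAAGGTCAAGGCCAAGGCCACCCTGACCGCCAACAATCGCAGCTGCACCGCCTACATGCAGTTGAGGACCGTCACCAGCGAGGAAAGCGCCGGGTACTACTGTACCAGA
>14-2
GAAGGGCAACTTCAGCACAGCGGCGCCGGGTGGGTTAAGCCCGGAGCCAGCGTGAAACTGAGGTGTACGGCCAGCACCTACACCTTCAGCTGCTACTGGATCAACTGGGATACGCACAGACCGGGCCATGGCCTGGAGTGGATCGGCAAGATCCTGCCCGGCAGCGGCATTACCTACTACAACGAGAAGGTCAAGGGCAAGGTCACCCTGACCTCCGACAAGAGCAATAGCACCGCTTACCTGCGGCTGACCAGCCTGACGACAGCGGAGAGCTCCGTGGACTACTGTTCCAGA
>2-2
AGGAAGAAGCTGCAGGAGAGCGCCGGCGAGCTGTTGGAGCGCGGCGACAGAGTGAAGCTGAGCTGTAAGGCCAGCGGTTACACCATCAACAGCTTCTGGATCAACTGGGTGAATCAGGGACCCAGCCGGGGCCTCGAGTGGATCGGCGAGATCCTGCCCGGCAGCTCCAGCTCCAACAACAACGCGAAATTCACAGGAGAAGCCACCCCGTCCGCCGACAAGAGCAGCAGGACCCGCTACATGCAGCTGACCAGCCTAACGAGCGGCGACAGCGCCGTGTTCTACTGTGTCAGA
>2-5
GAGGTACAGCTGCGGCAGAGCGGCGCCCACTTGGTGCAGCCCGGCGACAGCGTGAAGCTGAGGTGTAAGGCCATCGGCTACACCTTCATGCGCTGCTGGAACACCTGGGTGAAGAAGAGACACTGCCGTGGCCTAGCGTGGATCGCCACGATCCTGCCCGCCATCGGCAGCACCAACTACAACGAGGAGTTAGAGGGCCAGGCCACCCTGAACGCCGAGAAGAACAGAAGCATGGGCTACATGCAGCTGAGCAGCCTGACCAGCCAAGACAGCGCCGTGTACTACTGTGCCACA
>3-1
GAGGTTCAGCTGCAGCAGAGATGCGCCGAGATGGTGAAGCCCGACGCCAGCGCGACGATGAGCTGTAAGGCCTCCAGCTACACCTTCACCAGCTACTGGATCAACTGGGTGAACCAGCGACCCCGCCAGGGCCTGAAGTGGATCGGCGAGATCCTGCCCGGCACCTGGAGCACCAACAACAACAAGATGTACGAGGGCAAGGCCACCCTGTCCGCCGACAATAGTGGCAGGACCTCATACATGCAGCTCAGCAGCGTGACCAGCGGCGACAGCGCTGGGTGCTACTGTGCCAGA
>3-3
GAGGTGCTGCTGCAGCCGAGCGGCGCCGAGCTGATGAAGTCCGGCGCCAGTGTGAAGCTGAGCTGTAATGACGGCGGCTACACCTGCGCCAGGTACTTGAACAACTGGGTCAAGCAGAGACACGGGCAGGGCCTGGGGTGGATCGGCGAGATCCTCCCCGTCAGCCTCAGCAGAAACTACATCGAGAACTCCAAGGGCAAGGCCACCATGACCGCGGGCCAGAGCAGTAGCACCGCCTACATGCAGCTGCGCCGCCTGACCTGCGAGCACATCGCCGGACACTACTGTGCCAGA
>5-4
GAGGTGCATCTGACACAGGGCGGGGCGGAGCTAGTGAATACCCGCTCCAGCCTGAAGCTGAGCTGTAAGGCCAGGAGCTACACCATCACCAGCTACTGGAACAAATGGGTGATGCAGAGACCCGGCCCGGGCCTGGATTGGATCGGGGAGATACTGCCCGGCAGTGGCAGCCCCCACTACAACGAGAATTACAAAGGCAAGGCCACCCTGACCGCCGACAAAGTCAGCAGCACCGCCTACATGCTGGTGAGCAGCCTGACCTGCGAAGACAGCGCCGAGTACGACTGTGCCAGA
>5-6
GAGTTGCAGGTGCAGCAGACCGGCGCCGCGCTGGTGAAGCCCGGCGACACCGTGAAGGTGGGCTGTGAAACCAGGGGATATACCCTCACCTGCTACTCGATCAACTGGATGAAGCAGAAACCCGGCCAGGGCATGTTGTGGATCGGCGAGAGCCCGCCAGGCAGCGGCAGCGCCCACTACAACGAGAGGTTCAATGGCAAGGCCACCCTGCCCGCCGACATGAGCATCCGAACCGCCTACGTGCAGCTCAGCAGCCTGACCATCGAGGACACCGCCATGTACTACTGTGACAGA
>9-1
GAGGGGCAGCTGCAGGAGAGCGGCGACGAGCTGGTGATGCCCGGCGCCGGCGTCAAGCTGAACTCTAAGGCCAGGGGCCACACCTTCACCCGCAATTGGTTTAACTGGGTGACGGCAAGACTCGGCCCGGGTCCGGAGGGGATCGGCGAGATCCTGCCCGGCAGCGGCAGCTCTAACTACAACGCAACGTTCAAGGGCATGGCCGCCTTGACAGCCGACAATAGCAGCAGCACCGCCTACATGCAGCGGAGCAGCCTTACCTGTGAGGACAACGCCGCTTACTACTGTGCCAGA
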