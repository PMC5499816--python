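>slob_wt|1
GGCCGATAACGCGGCGTATGCGCAATGTCGAAGCATATTACGCATACGCCCCATCCGC
>slob_wt|2
GTTTGCTGTGGCGGATGGGGCGTATGCGTAATATGCTTCGACATTGCGCATACGCCGCGT
TATC
>slob_wt|3
CACAGCAAACGCTGCGTATGCGTAATACTTTGTGCACACGTTGCGTATGAGTAATGTCCT
>slob_wt|4
AATTAGGACATTACTCATACGCAACGTGTGCACAAAGTATTACGCATACGCAGC
>slob_mt|1
GGCCGATATCCCGGCCTTTGCCCTATGTCGAAGCATATAAGGCAAGGCCCGAACCGC
>slob_mt|2
GATTGCTGTGGCGGTTCGGGCCTTTGCCTTATATGCTTCGACATAGGGCAAAGGCCGGGA
TATC
>slob_mt|3
CACAGCAATCCCTGCCTTTGCCTTATACTTTGTGCACTCCTTGCCTTTGACTTATGTCCT
>slob_mt|4
AATTAGGACATAAGTCAAAGGCAAGGAGTGCACAAAGTATAAGGCAAAGGCAGG
>pdp1_wt|1
GGCCAGCACATTACGCATACGTCACGTGTTGCAAAAATAATACGTATACGACGCGTGTC
>pdp1_wt|2
TGGTACAGAAGACACGCGTCGTATACGTATTATTTTTGCAACACGTGACGTATGCGTAAT
GTGCT
>pdp1_wt|3
TTCTGTACCATGCGGCGTATGAGCAATCTGTTAATACGTTACCCATACGCCCCGTGGGCC
>pdp1_wt|4
AATTGGCCCACGGGGCGTATGGGTAACGTATTAACAGATTGCTCATACGCCGCA
>pdp1_mt|1
GGCCAGCACATAAGGCAAAGGTCAGGAGTTGCAAAAATAAAAGGTAAAGGACGGGAGTC
>pdp1_mt|2
AGGTACAGAAGACTCCCGTCCTTTACCTTTTATTTTTGCAACTCCTGACCTTTGCCTTAT
GTGCT
>pdp1_mt|3
TTCTGTACCTTCCGGCCTTTGACCTATCTGTTAATACGTAAGCCAAAGGCCCGGAGGGCC
>pdp1_mt|4
AATTGGCCCTCCGGGCCTTTGGCTTACGTATTAACAGATAGGTCAAAGGCCGGA
>pdp1_pse|1
GGCCAGCACATTACGCATACGTAACGTGTTGCAAAAATAATACGTATACGAAGCGTTTC
>pdp1_pse|2
TCGTACAGAAGAAACGCTTCGTATACGTATTATTTTTGCAACACGTTACGTATGCGTAAT
GTGCT
>pdp1_pse|3
TTCTGTACGATGGGGCGTATGAGCAATCTGTTAATACGTTACCCATACGCCGCGTTGGCC
>pdp1_pse|4
AATTGGCCAACGCGGCGTATGGGTAACGTATTAACAGATTGCTCATACGCCCCA
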