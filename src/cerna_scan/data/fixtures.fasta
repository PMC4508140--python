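>MRAK088388_sense qPCR primer
GCCCTCCTATCTGGTATCTTTGAA
>MRAK088388_antisense qPCR primer
GAGCTCTTCTCACCTGGATCATC
>MRAK081523_sense qPCR primer
CTGGCATTCTTGTCAGCTTGTT
>MRAK081523_antisense qPCR primer
GGCCCAGGTAGGGAGAGATATG
>N4bp2_sense qPCR primer
CGGGCTCAGGGAAATCCTTT
>N4bp2_antisense qPCR primer
TTGCTCGGTTCTGGTTCCAC
>Plxna4_sense qPCR primer
TTGGACCACGCAACACTCTT
>Plxna4_antisense qPCR primer
CTGTTGCTCCCACCCCTG
>beta-actin_sense qPCR primer
GGAGATTACTGCCCTGGCTCCTA
>beta-actin_antisense qPCR primer
GACTCATCGTACTCCTGCTTGCTG
>U6_sense qPCR primer
GCTTCGGCAGCACATATACTAAAAT
>U6_antisense qPCR primer
CGCTTCACGAATTTGCGTGTCAT
>MRAK088388_probe ISH oligonucleotide probe
GCTGAAGAATAGACTGTAAGCTTTTCAGACGGTGTATCAGAAACAAAATGTTTTTATGTG
>MRAK081523_probe ISH oligonucleotide probe
GAGCCCAGTTGTAACTTGGTAAAGGACCTTTGTTATAATTAATTGTATACCTGTGTATGT
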