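name	sense_seq	antisense_seq
MRAK088388	GCCCTCCTATCTGGTATCTTTGAA	GAGCTCTTCTCACCTGGATCATC
MRAK081523	CTGGCATTCTTGTCAGCTTGTT	GGCCCAGGTAGGGAGAGATATG
N4bp2	CGGGCTCAGGGAAATCCTTT	TTGCTCGGTTCTGGTTCCAC
Plxna4	TTGGACCACGCAACACTCTT	CTGTTGCTCCCACCCCTG
beta-actin	GGAGATTACTGCCCTGGCTCCTA	GACTCATCGTACTCCTGCTTGCTG
U6	GCTTCGGCAGCACATATACTAAAAT	CGCTTCACGAATTTGCGTGTCAT
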