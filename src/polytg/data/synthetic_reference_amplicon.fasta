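>synthetic_CFTR_intron9_amplicon length=427 note=synthetic_stand-in_for_the_primer-to-primer_region;tract=(TG)11T7;flanks=15bp;not_genomic_sequence
CCATGTGCTTTTCAAACTAATTGTCAACCATAAACGTATACAACATATGCGGGAATAACA
ATATCGTTAAGGGAATCTTGGGTTGTTACTAACGATAGATGAAACGCAGCTATATGCAGT
ACTAAGGAAATTGGGTATATGATCCAGGAGACAGAACGCTAACAAGAACCTGGTGAAGAC
AATCTGGCACAACCACCATGTGTGTGTGTGTGTGTGTGTGTTTTTTTAACAGCAAGGAAG
CAAACCAGCCAAGCGTAGTCTAACTACACGTATTCGGATTCCAGCTCAATGTACTAGGTT
ACATAACACTAGCAGCTATATCAAACAATACAAGTTAATCTAATCACCTGACATTAAGCG
TTACTAAATAGTTACCATTATAATGCTCTTGGGCAGGCAGAGATGTAGTGCTGGAAGGTA
TTTTTGG
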