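>red_deer_satellite_I_probe Southern blot probe, Cervus elaphus satellite I consensus, 725 bp
CAAGACGAAAGGATGTCTGAATCCCCTGTGGAGACCACAGAGAAAGACCTAGTTCCCCACCTCATCGCGA
CCGGAGGCCTCACATCCTTTGAAAACTCCAGAGGTACGCGGAGATCAGTGCCTCCAAAGGAGACGATGCC
TGACTCCTCGTGAAACTTGATAGGAGTCCCAGGATTCCTGTGGCACGTGGAAAGGGACCCTTGGTCTCCC
GCCTCAGCTGGAGAGGCGTCCCAATTGCCCTGCCAAGCCTCGAGGAGAATCCCGAGTTGTCCCTCGCAAC
TAGGCAGGAGTCCTGACGTCGCTGAAGAAACACGTGTGTGGAAGGGCCATCCCCGTCGTAACTCGAGAAT
ATACCCCAGGTTCCCGCCGCAACTCGAGAAAAACCATGAGACTTCCCCCTCGCCGCGAGATGAGGCCCGA
TTCCCCTGCACTGCGTGCAGAGCAATTCCGTGTTGCACATCACACATGAAAGGAGCCTTGATTTCCTTGA
TGGCACTCCAGAGAAACCCCAAGAACACTGTTTCAAGGCTAGAGGGATCCTGAGGTCACTGTAGCAACAC
GAAAGAGCTCCGTGGACCAAAAATCAACTCGAGATGAGAGGTTAGTCCCTGGCTTCGACTCCAGAGGAAT
ACCACCTTACCACAAGCACCTCAAGAGGAGGCTTCTCTCAGCTCTAGGTATGTGAGAGGGACCCTGAGTT
TGCGGCCTCAAGTGGAATGGACACC
>mouse_major_satellite_probe Southern blot probe, Mus musculus major satellite, 804 bp incl. vector flanks
CAGTGAGCGCGCGTAATACGACTCACTATAGGGCGAATTGGAGCTCCCGCGGTGCGGCCGCTCTAGAACT
AGTGGATCCCCCGGGCTGCAGCCCAATGTGGAATTCGCCCTTGGCGAGGAAAACTGAAAAAGGTGGAAAA
TTTAGAAATGTCCACTGTAGGACGTGGAATATGGCAAGAAAACTGAAAATCATGGAAAATGAGAAATATC
CACTTGACGACTTGAAAAATGACAAAATCCCTGAAAAACGTGAAAAATGAGAAATGCACACTGTAGGACC
TGGAATATGGCGAGAAAACTGAAAATCACGGAAAATGAGAAATACACACTTTAGGATGTGAAATATGGCG
AGGAAAACTGAAAAAGGTGGGAAATTTAGAAACGTCCACTGTAGGACGTGGAATATGGCAAGAGAACTGA
AAATCATGGAAAATGAGAAACATCCACTTGACGACTTGAAAAATGACGAAATCACTAAAAAACGTGAAAA
ATGAGAAATGCACACTGAAGGACCTGGAATATGGCGAGAAAACTGAAAATCACGGAAAATGAGAGATACA
CACTTTAGGACGTGAAATATGGCGAGGAAAACTGAAAAAGGTGGAAAATTTAGAAATGTCCTGTGTAGGA
CGTGGAATATGGCAAGAAAACTGAAAATCATGGAAAATGAGAAACATCCACTTGACGACTAAGGGCGAAT
TCCACAGTGGATATCAAGCTTATCGATACCGTCGACCTCGAGGGGGGGCCCGGTACCCAGCTTTTGTTCC
CTTTAGTGAGGGTTAATTGCGCGCTTGGCGTAAT
>mouse_major_satellite_fish_probe FISH oligo probe for mouse major satellite DNA
GGAAAATTTAGAAATGTCCACTG
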