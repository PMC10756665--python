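>hY1 synthetic YRNA-homolog stand-in, 112 nt, 10-nt 5'/3' stem complementarity
ACAATCGTAGTGGAGTGCGGCCATCGAACAATCACGACCCTCCGAAGTAGCGGGGCTTTG
AGCAATCGCTTTGAGCGTGAGACAGGCCCAACTTATATAATACTACGATTGT
>hY3 synthetic YRNA-homolog stand-in, 101 nt, 10-nt 5'/3' stem complementarity
AACCCCGTGTTCAACCGAATCGTGGGATTGATGGGGAACATCGTCCGCACTCAGTGCTAC
ACAAGTTCGAGCGCCGCCTGCACTAAAGTAGACACGGGGTT
>hY4 synthetic YRNA-homolog stand-in, 93 nt, 10-nt 5'/3' stem complementarity
TGTTAACCCGAGATAAGTCTCGGCACGTCTATGTGTACAGCGTTTACAGGCGCAGACGGT
TGACACGGGCGCGAGCGTGAGGACGGGTTAACA
>hY5 synthetic YRNA-homolog stand-in, 83 nt, 10-nt 5'/3' stem complementarity
TGAGTCCACTCGAATTAAATATAGAATTTGCGATAAGCTGTGTTATGCTATAAATCTCAG
GGTACCGAGCTGTAGTGGACTCA
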