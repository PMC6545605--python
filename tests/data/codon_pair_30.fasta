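>seq_a synthetic 30-codon alignment
ACCGTTGCTCGGCGGTCGACCGGGATAACCGAATTGGTAGTGGGTGTTCTTACTTCCCGTCTGCCGAGTTGTGTTGCTCGATCAGACCGT
>seq_b synthetic, evolved from seq_a
ACCGTTGCTCGGCGGTCGACCGGGATAACCGATTTGGTAGTAGGAGTTCTGACTTCGCGTCCGCCGAGATGTGTTGCTCGACCGGACCGT
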