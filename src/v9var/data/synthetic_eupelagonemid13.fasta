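>genome13_barcode_1;size=93 synthetic stand-in, most abundant V9 barcode
TCTTGCTGAAGTTCCTTCCTGCCGCTCTATTTATACCTAGGCAGCGAAATAAAAATTTACATCGTAGCATGCCAGCCTAGGACAAGCCAGTATCGAACGTACGCGTAGGCCATTGCATGGCCTTG
>genome13_barcode_2;size=86 synthetic stand-in, second V9 barcode (2 substitutions, identity 123/125 = 0.984)
TCTTGCTGAAGTTCCTTCCTGCCGCTCTATTTATACCTAGACAGCGAAATAAAAATTTACATCGTAGCATGCCAGCCTAGGACAAGCCGGTATCGAACGTACGCGTAGGCCATTGCATGGCCTTG
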