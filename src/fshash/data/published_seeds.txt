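# Published spaced seeds, all of weight 22.
# Q1-Q3: maximize the hit probability (span 31)
1111011101110010111001011011111
1111101011100101101110011011111
1111101001110101101100111011111
# Q4-Q6: minimize the overlap complexity (span 31)
1111010111010011001110111110111
1110111011101111010010110011111
1111101001011100111110101101111
# Q7-Q9: maximize the sensitivity (span 31)
1111011110011010111110101011011
1110101011101100110100111111111
1111110101101011100111011001111
# Q0: contiguous 22-mer
1111111111111111111111
# Q10: alternating match/don't-care, 22 match positions
1010101010101010101010101010101010101010101
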