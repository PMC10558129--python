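MEME version 4

ALPHABET= ACGT

Background letter frequencies
A 0.35000 C 0.15000 G 0.15000 T 0.35000

MOTIF INR
letter-probability matrix: alength= 4 w= 8 nsites= 20 E= 0
 0.050000 0.050000 0.050000 0.850000
 0.050000 0.850000 0.050000 0.050000
 0.850000 0.050000 0.050000 0.050000
 0.050000 0.050000 0.850000 0.050000
 0.050000 0.050000 0.050000 0.850000
 0.050000 0.850000 0.050000 0.050000
 0.050000 0.050000 0.050000 0.850000
 0.050000 0.050000 0.050000 0.850000

MOTIF TATA
letter-probability matrix: alength= 4 w= 8 nsites= 20 E= 0
 0.050000 0.050000 0.050000 0.850000
 0.850000 0.050000 0.050000 0.050000
 0.050000 0.050000 0.050000 0.850000
 0.850000 0.050000 0.050000 0.050000
 0.480000 0.050000 0.050000 0.420000
 0.850000 0.050000 0.050000 0.050000
 0.480000 0.050000 0.050000 0.420000
 0.480000 0.050000 0.420000 0.050000

MOTIF TF8
letter-probability matrix: alength= 4 w= 8 nsites= 20 E= 0
 0.030000 0.910000 0.030000 0.030000
 0.910000 0.030000 0.030000 0.030000
 0.030000 0.910000 0.030000 0.030000
 0.030000 0.030000 0.910000 0.030000
 0.030000 0.030000 0.030000 0.910000
 0.030000 0.030000 0.910000 0.030000
 0.910000 0.030000 0.030000 0.030000
 0.030000 0.910000 0.030000 0.030000
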