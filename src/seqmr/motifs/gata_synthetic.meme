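MEME version 4

ALPHABET= ACGT

strands: +

Background letter frequencies
A 0.25 C 0.25 G 0.25 T 0.25

MOTIF GATA synthetic consensus-derived stand-in (AGATAAGA)
letter-probability matrix: alength= 4 w= 8 nsites= 20 E= 0
 0.600 0.140 0.140 0.120
 0.020 0.020 0.940 0.020
 0.940 0.020 0.020 0.020
 0.020 0.020 0.020 0.940
 0.940 0.020 0.020 0.020
 0.850 0.050 0.050 0.050
 0.150 0.120 0.550 0.180
 0.450 0.180 0.220 0.150
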