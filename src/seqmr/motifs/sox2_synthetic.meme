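MEME version 4

ALPHABET= ACGT

strands: +

Background letter frequencies
A 0.25 C 0.25 G 0.25 T 0.25

MOTIF SOX2 synthetic consensus-derived stand-in (CCATTGTTC)
letter-probability matrix: alength= 4 w= 9 nsites= 20 E= 0
 0.150 0.450 0.200 0.200
 0.150 0.550 0.150 0.150
 0.900 0.030 0.040 0.030
 0.020 0.020 0.020 0.940
 0.020 0.020 0.020 0.940
 0.020 0.020 0.940 0.020
 0.020 0.020 0.020 0.940
 0.050 0.050 0.050 0.850
 0.200 0.450 0.150 0.200
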