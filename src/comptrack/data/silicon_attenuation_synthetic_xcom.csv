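# material: silicon (Z=14)
# density_g_per_cm3: 2.33
energy_keV,photo_cm2_per_g,incoherent_cm2_per_g,coherent_cm2_per_g
5.0,243.104,0.0626846,1.83379
6.0,145.4,0.0722054,1.52816
8.0,63.4428,0.0910354,1.14612
10.0,32.8674,0.105745,0.916893
15.0,9.70779,0.132166,0.500044
20.0,4.0261,0.148411,0.289484
30.0,1.14149,0.160529,0.133984
40.0,0.463454,0.160181,0.0775654
50.0,0.22845,0.159288,0.050762
60.0,0.131635,0.153165,0.0359
80.0,0.0529441,0.149073,0.0207831
100.0,0.026122,0.143777,0.0136013
150.0,0.00693665,0.131568,0.00629518
200.0,0.00268757,0.121168,0.00364439
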