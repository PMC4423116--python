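toxin,kd_nM,kd_sem_nM,ratio,ddg_kcal_mol
GxTx-1E(Nle),224,25,1.0,
E1A,414,38,1.8,0.36
G2A,297,50,1.3,0.17
E3A,125,62,0.6,-0.35
G5A,13652,320,60.9,2.44
G6A,379,51,1.7,0.31
F7A,89033,9413,397.4,3.55
W8A,9641,504,43.0,2.23
W9A,5837,1850,26.1,1.93
K10A,984,90,4.4,0.88
G12A,21755,1086,97.1,2.71
S13A,545,56,2.4,0.53
G14A,461,89,2.1,0.43
K15A,823,127,3.7,0.77
P16A,22967,2812,102.5,2.75
P20A,652,73,2.9,0.63
K21A,440,82,2.0,0.40
Y22A,35337,7464,157.7,3.00
V23A,516,60,2.3,0.50
S25A,1169,64,5.2,0.98
P26A,813,99,3.6,0.76
K27A,763,49,3.4,0.73
W28A,44298,2471,197.7,3.14
L30A,2474,278,11.0,1.42
N32A,1228,166,5.5,1.01
F33A,491,18,2.2,0.47
P34A,348,60,1.6,0.26
Nle35A,306,19.8,1.4,0.19
P36A,250,22,1.1,0.07
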