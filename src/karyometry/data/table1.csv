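population_id,pair_rank,homologue,mean_tl_um,sd_tl_um
CI,1,1,6.29,0.82
CI,1,2,6.06,0.83
CI,2,1,5.40,0.81
CI,2,2,5.03,0.76
CI,3,1,4.48,0.58
CI,3,2,4.28,0.51
CI,4,1,4.13,0.51
CI,4,2,4.04,0.50
CI,5,1,3.98,0.51
CI,5,2,3.91,0.51
CI,6,1,3.84,0.46
CI,6,2,3.76,0.45
CI,7,1,3.71,0.45
CI,7,2,3.64,0.45
CI,8,1,3.59,0.45
CI,8,2,3.52,0.40
CI,9,1,3.46,0.40
CI,9,2,3.41,0.39
CI,10,1,3.35,0.40
CI,10,2,3.18,0.45
TO,1,1,6.06,0.87
TO,1,2,5.77,0.81
TO,2,1,5.10,0.62
TO,2,2,4.92,0.59
TO,3,1,4.35,0.69
TO,3,2,4.23,0.66
TO,4,1,4.11,0.66
TO,4,2,4.05,0.63
TO,5,1,3.98,0.62
TO,5,2,3.92,0.61
TO,6,1,3.85,0.62
TO,6,2,3.77,0.61
TO,7,1,3.73,0.60
TO,7,2,3.70,0.58
TO,8,1,3.67,0.57
TO,8,2,3.60,0.56
TO,9,1,3.56,0.55
TO,9,2,3.50,0.53
TO,10,1,3.45,0.55
TO,10,2,3.40,0.54
BG,1,1,5.30,0.78
BG,1,2,4.93,0.77
BG,2,1,4.48,0.71
BG,2,2,4.34,0.70
BG,3,1,3.90,0.61
BG,3,2,3.80,0.54
BG,4,1,3.67,0.46
BG,4,2,3.59,0.46
BG,5,1,3.53,0.44
BG,5,2,3.46,0.44
BG,6,1,3.41,0.44
BG,6,2,3.38,0.43
BG,7,1,3.34,0.45
BG,7,2,3.31,0.44
BG,8,1,3.28,0.43
BG,8,2,3.26,0.43
BG,9,1,3.18,0.44
BG,9,2,3.13,0.41
BG,10,1,3.09,0.44
BG,10,2,3.00,0.46
MC,1,1,5.25,0.69
MC,1,2,4.90,0.61
MC,2,1,4.31,0.58
MC,2,2,4.10,0.57
MC,3,1,3.61,0.43
MC,3,2,3.53,0.45
MC,4,1,3.42,0.40
MC,4,2,3.30,0.42
MC,5,1,3.26,0.41
MC,5,2,3.21,0.40
MC,6,1,3.16,0.40
MC,6,2,3.10,0.36
MC,7,1,3.07,0.36
MC,7,2,3.04,0.38
MC,8,1,3.00,0.37
MC,8,2,2.98,0.36
MC,9,1,2.94,0.38
MC,9,2,2.91,0.37
MC,10,1,2.85,0.34
MC,10,2,2.70,0.39
CC,1,1,4.87,0.60
CC,1,2,4.58,0.63
CC,2,1,4.17,0.41
CC,2,2,3.80,0.37
CC,3,1,3.42,0.48
CC,3,2,3.34,0.40
CC,4,1,3.28,0.31
CC,4,2,3.21,0.32
CC,5,1,3.20,0.32
CC,5,2,3.14,0.29
CC,6,1,3.07,0.28
CC,6,2,3.04,0.29
CC,7,1,3.00,0.28
CC,7,2,2.99,0.29
CC,8,1,2.96,0.28
CC,8,2,2.92,0.29
CC,9,1,2.89,0.29
CC,9,2,2.80,0.26
CC,10,1,2.77,0.27
CC,10,2,2.62,0.25
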