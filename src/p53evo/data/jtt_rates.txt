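# Jones-Taylor-Thornton (JTT) amino-acid replacement model (Jones et al. 1992,
# CABIOS 8:275-282), as tabulated for likelihood software (e.g. PAML jones.dat).
# Residue order: A R N D C Q E G H I L K M F P S T W Y V
# Block 1: 190 exchangeabilities, column-major lower triangle
#   (S[r,a], S[n,a], ..., S[v,a], S[n,r], ..., S[v,y]).
# Block 2: 20 equilibrium frequencies, same residue order.
58 54 81 56 57 105 179 27 36 30
35 54 15 194 378 475 9 11 298 45
16 113 310 29 137 328 22 38 646 44
5 74 101 64 126 20 17 528 34 86
58 81 391 47 12 263 30 10 15 503
232 8 70 16 10 49 767 130 112 11
7 26 15 4 15 59 38 4 46 31
9 5 59 69 17 23 7 31 78 14
223 42 115 209 62 323 26 597 9 72
292 43 4 164 53 51 18 24 20 119
26 12 9 181 18 5 18 30 32 10
7 45 23 6 6 27 14 5 24 201
33 55 8 47 16 56 45 33 40 115
73 46 8 573 11 229 21 479 89 10
40 245 9 32 961 14 388 248 102 59
25 52 24 180 65 4 21 47 103 10
8 14 43 16 29 226 24 18 323 17
92 12 53 536 62 285 118 6 10 23
477 35 63 38 12 21 112 71 25 16

0.0767479232521 0.0516909483091 0.0426449573550 0.0515439484561 0.0198029801970
0.0407519592480 0.0618299381701 0.0731519268481 0.0229439770560 0.0537609462391
0.0919039080961 0.0586759413241 0.0238259761740 0.0401259598740 0.0509009490991
0.0687649312351 0.0585649414351 0.0142609857390 0.0321019678980 0.0660049339951
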