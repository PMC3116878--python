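# SYNTHETIC CAT10-style profile library: medoids of k-means
# clusters of simulated sparse per-site residue profiles. NOT the
# published empirical profile set; a labelled stand-in with the same
# structure (low-diversity equilibrium frequency profiles + weights).
A R N D C Q E G H I L K M F P S T W Y V
0.108800 0.000100 0.000100 0.000100 0.000100 0.042398 0.390750 0.000100 0.000100 0.351045 0.000100 0.000100 0.058861 0.000100 0.000100 0.000100 0.000100 0.000100 0.000100 0.000100 0.155449
0.056400 0.000100 0.000100 0.000100 0.000100 0.000100 0.000100 0.000100 0.000100 0.070229 0.057706 0.124697 0.000100 0.628193 0.000100 0.000100 0.117676 0.000100 0.000100 0.000100 0.000100
0.058800 0.000100 0.000100 0.000100 0.020196 0.000100 0.000100 0.000100 0.584918 0.000100 0.076963 0.000100 0.000100 0.000100 0.000100 0.000100 0.147375 0.169049 0.000100 0.000100 0.000100
0.059200 0.000100 0.639643 0.116611 0.000100 0.000100 0.000100 0.000100 0.000100 0.000100 0.000100 0.000100 0.000100 0.000100 0.000100 0.000100 0.067322 0.133086 0.000100 0.000100 0.041840
0.337800 0.000100 0.000100 0.000100 0.241547 0.000100 0.000100 0.159246 0.000100 0.000100 0.000100 0.000100 0.100898 0.000100 0.000100 0.000100 0.182117 0.000100 0.000100 0.000100 0.314695
0.058800 0.000100 0.000100 0.000100 0.000100 0.000100 0.000100 0.000100 0.000100 0.000100 0.000100 0.000100 0.133043 0.096040 0.635357 0.000100 0.000100 0.000100 0.033486 0.000100 0.100576
0.059400 0.000100 0.000100 0.000100 0.000100 0.142637 0.000100 0.000100 0.000100 0.000100 0.000100 0.622729 0.124197 0.000100 0.000100 0.000100 0.000100 0.051673 0.000100 0.000100 0.057266
0.057400 0.000100 0.000100 0.000100 0.000100 0.000100 0.000100 0.000100 0.000100 0.000100 0.000100 0.000100 0.000100 0.000100 0.059235 0.000100 0.117275 0.143751 0.634704 0.000100 0.043537
0.105000 0.123297 0.000100 0.000100 0.000100 0.000100 0.000100 0.000100 0.000100 0.000100 0.000100 0.000100 0.000100 0.025018 0.000100 0.000100 0.000100 0.283671 0.111072 0.455445 0.000100
0.098400 0.000100 0.000100 0.000100 0.000100 0.438450 0.000100 0.000100 0.000100 0.084070 0.355817 0.000100 0.000100 0.000100 0.049871 0.000100 0.000100 0.070295 0.000100 0.000100 0.000100
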