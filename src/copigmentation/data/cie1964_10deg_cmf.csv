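# CIE 1964 10-degree standard observer colour-matching functions, 5 nm steps.
# Values generated from the Wyman, Sloan & Shirley (2013) analytic sum-of-Gaussian
# fits to the 1964 observer (accuracy ~1% of peak per channel); adequate for the
# qualitative transmittance colorimetry in this package, not for standards work.
# columns: wavelength_nm, xbar, ybar, zbar
wavelength_nm,xbar,ybar,zbar
380,0.001995,0.000694,0.002562
385,0.004528,0.001044,0.008464
390,0.009557,0.001551,0.023845
395,0.018781,0.002278,0.058243
400,0.034397,0.003306,0.125171
405,0.058778,0.004742,0.239721
410,0.093810,0.006723,0.413717
415,0.139980,0.009419,0.649766
420,0.195482,0.013043,0.936768
425,0.255744,0.017851,1.249300
430,0.313756,0.024145,1.551782
435,0.361317,0.032278,1.806234
440,0.390950,0.042646,1.980932
445,0.397855,0.055686,2.057066
450,0.381205,0.071865,2.031554
455,0.344310,0.091662,1.915763
460,0.293609,0.115548,1.731236
465,0.236933,0.143957,1.504157
470,0.181674,0.177258,1.260215
475,0.133444,0.215714,1.020912
480,0.095514,0.259447,0.801676
485,0.068981,0.308405,0.611587
490,0.053413,0.362320,0.454221
495,0.047623,0.420692,0.329042
500,0.050328,0.482766,0.232900
505,0.060579,0.547531,0.161332
510,0.077934,0.613734,0.109534
515,0.102454,0.679911,0.072988
520,0.134578,0.744430,0.047794
525,0.174949,0.805556,0.030792
530,0.224222,0.861525,0.019538
535,0.282873,0.910626,0.012223
540,0.351011,0.951288,0.007546
545,0.428216,0.982163,0.004602
550,0.513399,1.002203,0.002774
555,0.604703,1.010713,0.001654
560,0.699473,1.007395,0.000976
565,0.794301,0.992366,0.000571
570,0.885170,0.966148,0.000331
575,0.967680,0.929642,0.000190
580,1.037373,0.884072,0.000108
585,1.090095,0.830921,0.000061
590,1.122396,0.771848,0.000035
595,1.131880,0.708605,0.000019
600,1.117491,0.642949,0.000011
605,1.079663,0.576565,0.000006
610,1.020329,0.510999,0.000003
615,0.942763,0.447603,0.000002
620,0.851279,0.387494,0.000001
625,0.750828,0.331541,0.000001
630,0.646539,0.280355,0.000000
635,0.543270,0.234305,0.000000
640,0.445224,0.193532,0.000000
645,0.355675,0.157989,0.000000
650,0.276823,0.127467,0.000000
655,0.209789,0.101641,0.000000
660,0.154720,0.080102,0.000000
665,0.110978,0.062390,0.000000
670,0.077373,0.048027,0.000000
675,0.052400,0.036539,0.000000
680,0.034451,0.027475,0.000000
685,0.021973,0.020418,0.000000
690,0.013587,0.014996,0.000000
695,0.008139,0.010886,0.000000
700,0.004720,0.007809,0.000000
705,0.002648,0.005537,0.000000
710,0.001436,0.003880,0.000000
715,0.000752,0.002687,0.000000
720,0.000380,0.001840,0.000000
725,0.000185,0.001244,0.000000
730,0.000087,0.000832,0.000000
735,0.000039,0.000550,0.000000
740,0.000017,0.000359,0.000000
745,0.000007,0.000232,0.000000
750,0.000003,0.000148,0.000000
755,0.000001,0.000093,0.000000
760,0.000000,0.000058,0.000000
765,0.000000,0.000036,0.000000
770,0.000000,0.000022,0.000000
775,0.000000,0.000013,0.000000
780,0.000000,0.000008,0.000000
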