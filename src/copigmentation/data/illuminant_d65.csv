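# CIE standard illuminant D65, relative spectral power distribution, 5 nm steps,
# normalised to 100 at 560 nm. Transcribed (2 dp) from the standard published table.
# columns: wavelength_nm, relative_power
wavelength_nm,relative_power
380,49.98
385,52.31
390,54.65
395,68.70
400,82.75
405,87.12
410,91.49
415,92.46
420,93.43
425,90.06
430,86.68
435,95.77
440,104.86
445,110.94
450,117.01
455,117.41
460,117.81
465,116.34
470,114.86
475,115.39
480,115.92
485,112.37
490,108.81
495,109.08
500,109.35
505,108.58
510,107.80
515,106.30
520,104.79
525,106.24
530,107.69
535,106.05
540,104.41
545,104.23
550,104.05
555,102.02
560,100.00
565,98.17
570,96.33
575,96.06
580,95.79
585,92.24
590,88.69
595,89.35
600,90.01
605,89.80
610,89.60
615,88.65
620,87.70
625,85.49
630,83.29
635,83.49
640,83.70
645,81.86
650,80.03
655,80.12
660,80.21
665,81.25
670,82.28
675,80.28
680,78.28
685,74.00
690,69.72
695,70.67
700,71.61
705,72.98
710,74.35
715,67.98
720,61.60
725,65.74
730,69.89
735,72.49
740,75.09
745,69.34
750,63.59
755,55.01
760,46.42
765,56.61
770,66.81
775,65.09
780,63.38
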