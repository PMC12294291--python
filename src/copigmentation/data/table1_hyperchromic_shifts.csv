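# Published short-term study results: mean hyperchromic shifts (A-A0)/A0 at 523 nm for
# Mv-3-O-glc (5e-5 M final) with each copigment at final molar ratios 1:1/1:5/1:10/1:20
# (final copigment concentrations 5e-5, 2.5e-4, 5e-4, 1e-3 M), plus the printed
# regression diagnostics (r2), stoichiometry n and dG0 (kJ/mol) for each pH condition.
copigment,pH,shift_1_1,shift_1_5,shift_1_10,shift_1_20,r2_printed,n_printed,dG0_printed
CAF,2.8,0.0097,0.0326,0.0568,0.0906,0.999,0.76,-7.05
CAF,3.2,0.0174,0.0640,0.0814,0.1628,0.985,0.74,-7.92
CAF,3.6,0.0217,0.0696,0.1304,0.2435,0.996,0.85,-10.40
CAF,3.8,0.0189,0.0472,0.0755,0.1226,0.982,0.63,-5.31
CA,2.8,0.0152,0.0455,0.0732,0.0972,0.996,0.64,-5.26
CA,3.2,0.0197,0.0590,0.0927,0.1573,0.996,0.69,-7.12
CA,3.6,0.0435,0.1304,0.2043,0.2826,0.991,0.64,-7.89
CA,3.8,0.0189,0.0566,0.0755,0.1509,0.987,0.67,-6.56
SI,2.8,0.0214,0.0671,0.1031,0.1425,0.991,0.65,-6.38
SI,3.2,0.0184,0.0642,0.1055,0.1683,0.998,0.75,-8.38
SI,3.6,0.0294,0.1131,0.1819,0.2593,0.988,0.76,-9.56
SI,3.8,0.0189,0.0736,0.1129,0.1501,0.978,0.71,-7.77
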