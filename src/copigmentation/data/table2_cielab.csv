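# Published long-term study results: CIELab records (D65 / 10-degree observer) of the
# model-wine solutions after 12 months (T12) per copigment, pH and molar ratio, plus the
# Mv-3-O-glc-only controls at time zero (T0). C* and H* are the instrument-printed chroma
# and hue angle; molar_ratio is copigment:pigment (empty for controls).
copigment,pH,timepoint,molar_ratio,C,H,L,a,b
none,2.8,T0,,29.29,-1.12,84.44,29.29,-0.57
none,3.2,T0,,12.84,0.09,91.31,12.84,0.02
none,3.6,T0,,7.56,15.10,93.75,7.30,1.97
none,3.8,T0,,3.41,18.13,96.98,3.24,1.06
CAF,2.8,T12,1,29.79,31.51,86.40,25.44,15.50
CAF,2.8,T12,5,24.84,31.51,89.10,21.20,12.95
CAF,2.8,T12,10,18.20,31.51,91.50,15.48,9.58
CAF,2.8,T12,20,8.15,39.53,95.50,6.28,5.20
CAF,3.2,T12,1,24.19,28.07,88.50,21.33,11.42
CAF,3.2,T12,5,20.89,29.79,90.30,18.14,10.36
CAF,3.2,T12,10,16.27,30.94,92.20,13.94,8.38
CAF,3.2,T12,20,7.57,42.40,95.40,5.60,5.09
CAF,3.6,T12,1,22.51,28.07,89.20,19.91,10.51
CAF,3.6,T12,5,19.64,29.22,90.70,17.10,9.66
CAF,3.6,T12,10,14.38,31.51,89.30,12.26,7.51
CAF,3.6,T12,20,7.69,42.40,95.90,5.65,5.21
CAF,3.8,T12,1,10.69,37.24,95.80,8.49,6.50
CAF,3.8,T12,5,9.44,35.52,96.30,7.68,5.49
CAF,3.8,T12,10,9.21,35.52,96.70,7.47,5.38
CAF,3.8,T12,20,4.78,48.13,98.50,3.20,3.55
CA,2.8,T12,1,24.54,78.50,93.50,4.79,24.07
CA,2.8,T12,5,18.46,76.20,93.80,4.47,17.91
CA,2.8,T12,10,15.35,75.06,94.30,3.95,14.83
CA,2.8,T12,20,12.83,73.34,95.30,3.73,12.28
CA,3.2,T12,1,22.71,83.65,94.20,2.47,22.58
CA,3.2,T12,5,20.15,84.80,94.70,1.86,20.07
CA,3.2,T12,10,13.09,77.92,95.50,2.76,12.79
CA,3.2,T12,20,5.79,55.58,96.20,3.28,4.77
CA,3.6,T12,1,26.86,84.22,93.50,2.69,26.72
CA,3.6,T12,5,23.02,85.37,94.10,1.83,22.95
CA,3.6,T12,10,20.27,85.94,95.30,1.48,20.22
CA,3.6,T12,20,13.74,79.07,95.60,2.61,13.49
CA,3.8,T12,1,22.87,89.38,96.20,0.31,22.87
CA,3.8,T12,5,16.42,92.25,97.70,-0.63,16.41
CA,3.8,T12,10,11.97,92.25,98.40,-0.45,11.96
CA,3.8,T12,20,7.62,85.94,98.30,0.55,7.60
SI,2.8,T12,1,7.11,43.54,95.60,5.14,4.91
SI,2.8,T12,5,6.81,45.26,96.00,4.80,4.83
SI,2.8,T12,10,7.30,46.98,96.00,4.98,5.33
SI,2.8,T12,20,6.98,46.41,95.90,4.80,5.08
SI,3.2,T12,1,6.15,57.87,96.50,3.29,5.19
SI,3.2,T12,5,5.97,57.30,96.40,3.25,5.01
SI,3.2,T12,10,6.23,55.00,96.00,3.58,5.10
SI,3.2,T12,20,6.12,56.72,96.30,3.37,5.10
SI,3.6,T12,1,6.11,54.43,96.20,3.53,4.98
SI,3.6,T12,5,5.84,55.58,96.20,3.32,4.81
SI,3.6,T12,10,6.20,52.14,95.80,3.79,4.91
SI,3.6,T12,20,6.70,53.86,96.20,3.93,5.42
SI,3.8,T12,1,3.64,67.04,99.00,1.43,3.35
SI,3.8,T12,5,3.45,67.61,99.60,1.30,3.19
SI,3.8,T12,10,3.70,65.89,99.00,1.53,3.37
SI,3.8,T12,20,3.43,63.03,98.80,1.54,3.06
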