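# Published long-term study results: Abs 440/510 nm ratio of the Mv-3-O-glc/CA solutions
# after 12 months of storage, mean +- SD over triplicates per pH and molar ratio, with the
# printed Tukey letter (within each pH row; groups sharing a letter do not differ at
# alpha = 0.05).
pH,molar_ratio,mean,sd,letter
2.8,1,2.29,0.01,b
2.8,5,2.40,0.01,c
2.8,10,2.39,0.01,c
2.8,20,1.89,0.00,a
3.2,1,2.28,0.01,b
3.2,5,2.40,0.02,c
3.2,10,2.40,0.00,c
3.2,20,1.91,0.05,a
3.6,1,2.28,0.01,b
3.6,5,2.39,0.00,c
3.6,10,2.39,0.01,c
3.6,20,1.89,0.01,a
3.8,1,2.29,0.00,b
3.8,5,2.40,0.00,c
3.8,10,2.40,0.03,c
3.8,20,1.90,0.02,a
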