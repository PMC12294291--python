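# Upper 5% critical values q(0.05; k, df) of the studentized range distribution,
# transcribed (2 dp) from the standard printed table. Used only as a cross-check
# fixture for the numerically evaluated quantiles; never consulted by the fits.
k,df,q_crit_05
2,5,3.64
3,5,4.60
4,5,5.22
5,5,5.67
6,5,6.03
2,10,3.15
3,10,3.88
4,10,4.33
5,10,4.65
6,10,4.91
2,20,2.95
3,20,3.58
4,20,3.96
5,20,4.23
6,20,4.45
2,30,2.89
3,30,3.49
4,30,3.85
5,30,4.10
6,30,4.30
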