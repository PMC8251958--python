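label,donor,acceptor,D0_mM,B0_mM,P0_mM,K_donor,K_product,observed_conversion_pct
1a,a,1,5,1,0.09,,9.37,30.5
1b,b,1,5,1,0.09,,6.07,30
2a,a,2,5,1,0.09,,6.75,35
2b,b,2,5,1,0.09,,4.85,33
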