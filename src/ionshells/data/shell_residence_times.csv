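shell_range,tau1_ps,tau2_ps,rel_rms_error
d<0.35,1.389,2670.862,0.742
0.35<d<0.6,3.611,212.193,0.663
0.6<d<0.85,1.388,22.131,0.164
0.85<d<1.1,1.072,14.341,0.057
1.1<d<1.35,0.969,13.516,0.269
1.35<d<1.6,1.145,13.774,0.183
1.6<d<1.85,1.631,15.502,0.123
1.85<d<2.1,1.876,14.695,0.223
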