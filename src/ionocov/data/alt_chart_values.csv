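symbol,charge,ic,x_ic,i_av,n_star_rc_inv,provenance
Be,2,2.252,1.315,13.76,2.238,diagonal charts; alternative Be radius 0.889
B,3,3.291,1.743,23.800,2.488,diagonal charts
C,4,4.320,2.167,37.015,2.618,diagonal charts
N,5,5.554,2.675,53.406,2.803,diagonal charts; alternative N radius 0.710
O,6,6.939,3.246,72.020,3.015,diagonal charts; alternative O radius 0.660
Mg,2,1.933,1.184,11.325,2.119,diagonal charts
Al,3,2.730,1.418,17.763,2.189,diagonal charts
Si,4,3.371,1.776,25.763,2.449,diagonal charts
P,5,4.355,2.181,35.358,2.701,diagonal charts
S,6,5.165,2.515,46.077,2.806,diagonal charts
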