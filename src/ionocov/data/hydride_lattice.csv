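compound,symbol,charge,z_star,i_av,rc_inv,n_star_rc_inv,x_ic,ic,u_kj_mol
LiH,Li,1,1.253,5.39,0.816,2.238,0.808,1.023,905.4
NaH,Na,1,1.777,5.14,0.636,1.838,0.853,1.13,810.9
KH,K,1,1.949,4.34,0.513,1.769,0.799,0.999,714.2
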