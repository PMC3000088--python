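group,compound,symbol,charge,z_star,i_av,rc_inv,n_star_rc_inv,x_ic,ic,melting_point_c
1,KBr,K,1,1.949,4.34,0.513,1.769,0.799,0.999,730
1,CaBr2,Ca,2,2.807,9.005,0.576,1.987,1.053,1.617,765
2,CsF,Cs,1,2.332,3.89,0.41,1.787,0.781,0.956,684
2,BaF2,Ba,2,3.26,7.605,0.505,2.201,1.065,1.646,1280
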