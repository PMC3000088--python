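group,compound,symbol,charge,z_star,i_av,rc_inv,n_star_rc_inv,x_ic,ic,melting_point_c
1,KF,K,1,1.949,4.34,0.513,1.769,0.799,0.999,880
1,AgF,Ag,1,2.874,7.58,0.747,2.875,1.271,2.147,435
2,CaCl2,Ca,2,2.807,9.005,0.576,1.987,1.053,1.617,772
2,HgCl2,Hg,2,4.49,14.82,0.694,3.008,1.672,3.118,276
3,CaCl2,Ca,2,2.807,9.005,0.576,1.987,1.053,1.617,772
3,BeCl2,Be,2,2.002,13.76,1.125,2.238,1.315,2.252,405
4,NaBr,Na,1,1.777,5.14,0.636,1.838,0.853,1.13,755
4,MgBr2,Mg,2,2.637,11.33,0.733,2.119,1.184,1.933,700
4,AlBr3,Al,3,3.303,17.76,0.826,2.388,1.512,2.73,97.5
5,KBr,K,1,1.949,4.34,0.513,1.769,0.799,0.999,730
5,CaBr2,Ca,2,2.807,9.005,0.576,1.987,1.053,1.617,765
6,CsF,Cs,1,2.332,3.89,0.41,1.787,0.781,0.956,684
6,BaF2,Ba,2,3.26,7.605,0.505,2.201,1.065,1.646,1280
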