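group,compound,symbol,charge,z_star,i_av,rc_inv,n_star_rc_inv,x_ic,ic,u_kj_mol
1,LiH,Li,1,1.253,5.39,0.816,2.238,0.808,1.023,905.4
1,NaH,Na,1,1.777,5.14,0.636,1.838,0.853,1.13,810.9
1,KH,K,1,1.949,4.34,0.513,1.769,0.799,0.999,714.2
2,AgF,Ag,1,2.874,7.58,0.747,2.875,1.271,2.147,954
2,NaF,Na,1,1.777,5.14,0.636,1.838,0.853,1.13,903.9
2,KF,K,1,1.949,4.34,0.513,1.769,0.799,0.999,801.2
3,AgCl,Ag,1,2.874,7.58,0.747,2.875,1.271,2.147,904
3,TlCl,Tl,1,2.922,6.11,0.646,2.815,1.164,1.887,732
3,KCl,K,1,1.949,4.34,0.513,1.769,0.799,0.999,697.9
3,RbCl,Rb,1,2.134,4.18,0.455,1.75,0.787,0.97,677.8
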