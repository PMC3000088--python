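symbol,charge,n_star,z_star,r_c,rc_inv,n_star_rc_inv,i_av,x_ic,ic
Cu,3,3.45,4.349,1.11,0.901,3.108,21.610,1.885,3.918
Ag,3,3.85,4.81,1.339,0.747,2.875,21.227,1.867,3.592
Au,3,4.36,5.297,1.336,0.749,3.263,18.77,2.021,3.965
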