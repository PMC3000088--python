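d_n,u_kj_mol,ic
0,2260,1.617
2,2500,2.258
3,2580,2.502
4,2580,2.723
5,2550,2.719
6,2650,2.786
7,2700,2.874
8,2790,3.029
9,2840,3.155
10,2760,2.772
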