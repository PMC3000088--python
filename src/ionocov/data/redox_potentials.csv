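d_n,e0_v,ic
0,-2.87,1.617
2,-1.63,2.258
3,-1.18,2.502
4,-0.971,2.723
5,-1.19,2.719
6,-0.44,2.786
7,-0.28,2.874
8,-0.25,3.029
9,0.34,3.155
10,-0.76,2.772
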