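oxidation_state,delta_mm_s,z_star,ic
1,2.3,2.624,2.253
2,1.5,3.245,2.786
3,0.7,3.997,3.431
4,0.2,4.896,4.203
5,-0.6,5.684,4.879
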