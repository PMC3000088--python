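symbol,charge,i_z,i_av,x_ic,ic,estimated
Tl,1,6.11,6.11,1.16,1.89,0
Tl,2,20.4,13.26,1.59,2.92,1
Tl,3,29.8,18.77,1.75,3.31,0
Pb,2,15,11.21,1.45,2.58,0
Pb,3,32,18.14,1.74,3.44,1
Pb,4,42.3,24.18,1.94,3.78,0
Bi,3,25.6,16.63,1.69,3.16,0
Bi,4,45.3,23.72,1.95,3.81,1
Bi,5,56,30.18,2.15,4.27,0
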