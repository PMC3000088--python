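symbol,charge,ic,x_ic,log_beta_en,log_beta_edta
Mn,2,2.719,1.507,5.7,13.8
Fe,2,2.786,1.535,9.5,14.3
Co,2,2.874,1.571,13.8,16.3
Ni,2,3.029,1.635,18.6,18.6
Cu,2,3.155,1.687,18.7,18.7
Zn,2,2.772,1.529,12.1,16.1
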