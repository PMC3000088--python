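symbol,ie_order,energy_ev
H,1,13.600
Be,1,9.32
Be,2,18.20
C,1,11.26
C,2,24.40
C,3,47.90
C,4,64.50
N,1,14.53
N,2,29.6
N,3,47.5
N,4,77.5
N,5,97.9
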