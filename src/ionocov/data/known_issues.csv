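symbol,charge,column,reason
Hf,3,n_star_rc_inv,printed 2.024 inconsistent with n*/r_c = 3.024 (digit typo; the 4+ row prints 3.024)
Hf,2,n_star_rc_inv,printed 2.024 inconsistent with n*/r_c = 3.024 (digit typo; the 4+ row prints 3.024)
Po,4,x_z,printed 0.775 equals the bare X_z intercept; the slope term is missing (recomputation gives 1.521)
At,5,i_z,printed I_z 88.291 duplicates the 7+ row's value; derived X_z is internally consistent with it but physically implausible
Lw,3,r_c,r_c and its printed inverse are both exactly 1.000; row is internally consistent only via the Z*-direct pathway
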