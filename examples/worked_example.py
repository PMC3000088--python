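"""Derive every IC quantity for a cation from its ionization-energy ladder.

Walks the three-step hybrid bonding procedure for Be2+: average the first
two successive ionization energies into the hybrid ionicity I_av, convert
to an effective nuclear charge Z*, and localize it at the covalent radius
to get the ionocovalency IC and the X_IC electronegativity.
"""

import ionocov as ic

ladder = ic.IonizationLadder("Be", (9.32, 18.20))  # 1st, 2nd IE in eV
rec = ic.build_cation(ladder, k=2, n_star=1.99, r_c=0.970)

print(f"hybrid ionicity I_av = {rec.i_av:.3f} eV   (mean of the first 2 IEs)")
print(f"ultimate IE     I_z  = {rec.i_z:.3f} eV")
print(f"Z* = n*(I_av/R)^1/2  = {rec.z_star:.3f}")
print(f"IC = Z*/r_c          = {rec.ic:.3f}      (ionocovalent potential, 1/Angstrom)")
print(f"X_IC                 = {rec.x_ic:.3f}      (electronegativity on the IC scale)")
print(f"X_z (IC-force scale) = {rec.x_z:.3f}")
print(f"classification       = {rec.classify().label}")
print()
print("IC 2.064 marks the lower edge of the borderline band: beryllium is the")
print("weakest 'borderline' cation; anything below it is classed ionic.")
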