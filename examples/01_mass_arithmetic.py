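"""Worked mass example: cycloviolacin O2.

Computes the cyclic monoisotopic mass of a three-disulfide cyclotide, the
mass after reduction + carbamidomethylation of its six cysteines, and the
2+/3+ ion m/z values an LC-MS instrument would show.
"""

from cyclomine import alkylation_delta, monoisotopic_mass, mz_for_charge

CYO2 = "GIPCGESCVWIPCISSAIGCSCKSKVCYRN"

M = monoisotopic_mass(CYO2, topology="cyclic", n_disulfide=3)
print(f"cycloviolacin O2  ({len(CYO2)} residues, cyclic, 3 disulfides)")
print(f"  monoisotopic mass      : {M:.1f} Da")
print(f"  after alkylation (6 C) : {M + alkylation_delta(6):.1f} Da  (+{alkylation_delta(6):.2f})")
print(f"  [M+2H]2+               : {mz_for_charge(M, 2):.1f}")
print(f"  [M+3H]3+               : {mz_for_charge(M, 3):.1f}")
print()
print("The +348.18 Da shift confirms three disulfide bonds: each of the six")
print("cysteines gains one hydrogen (reduction) and one carbamidomethyl group.")
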