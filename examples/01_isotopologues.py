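"""Isotopologue chemistry of a biosynthetically 13C-labeled nucleoside.

Computes the [M+H]+ of 2'-O-methyladenosine in its unlabeled and uniformly
13C-labeled forms, its MRM transition, the natural-abundance satellite
pattern, and the labeling efficiency recovered from a labeled spectrum.
"""
from silis import chem

registry = chem.default_registry()
am = registry["Am"]

mz12 = chem.protonated_mz(am)
mz13 = chem.protonated_mz(am, uniform_13c=True)
print(f"Am [M+H]+ unlabeled : {mz12:.1f}")
print(f"Am [M+H]+ 13C       : {mz13:.1f}  (shift {round(mz13 - mz12)} = carbon count)")

prec, prod = chem.mrm_transition(am)
print(f"MRM transition      : {prec:.1f} -> {prod:.1f}  (methylribose loss)")

nat = chem.isotopologue_pattern(am, chem.NATURAL_13C_ABUNDANCE)
print(f"natural M+1/M ratio : {nat.ratio(1, 0):.4f}  (the ~12% satellite of 11 carbons)")

labeled = chem.isotopologue_pattern(am, 0.99)
ratio = labeled.ratio(10, 11)
p = chem.estimate_labeling_efficiency(ratio, am.n_carbon)
print(f"labeled M-1/M ratio : {ratio:.4f} -> labeling efficiency {100 * p:.0f}%")

# The mass shift equals the carbon count, so the labeled internal standard
# is fully resolved from the analyte while co-eluting with it; the ~99%
# efficiency means only a tiny M-1 residual leaks toward lighter masses.
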