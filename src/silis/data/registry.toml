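# Built-in nucleoside registry.
#
# One table per nucleoside: neutral elemental formula, parent canonical
# nucleoside, and flags controlling the derived MRM transition
# (2'-O-methylated species lose methylribose; C-glycosides have no
# derivable sugar-loss transition and must be given a transition_override
# by the user before a method export).  Retention-time windows are
# illustrative defaults for a ~20 min RP-18 gradient, not instrument
# calibrations.  The five species flagged no_external_calibration are
# detectable but not available as weighable pure substance, so no external
# calibration (hence no rRFN) can be established for them.

[C]
full_name = "cytidine"
formula = "C9H13N3O5"
rt_window = [2.6, 3.6]

[U]
full_name = "uridine"
formula = "C9H12N2O6"
rt_window = [3.5, 4.5]

[G]
full_name = "guanosine"
formula = "C10H13N5O5"
rt_window = [5.5, 6.5]

[A]
full_name = "adenosine"
formula = "C10H13N5O4"
rt_window = [9.0, 10.0]

[m5C]
full_name = "5-methylcytidine"
formula = "C10H15N3O5"
parent = "C"
rt_window = [4.6, 5.6]

[Cm]
full_name = "2'-O-methylcytidine"
formula = "C10H15N3O5"
parent = "C"
two_prime_methyl = true
rt_window = [5.6, 6.6]

[s4U]
full_name = "4-thiouridine"
formula = "C9H12N2O5S"
parent = "U"
rt_window = [10.5, 11.5]

[m5s2U]
full_name = "5-methyl-2-thiouridine"
formula = "C10H14N2O5S"
parent = "U"
rt_window = [12.5, 13.5]

[m7G]
full_name = "7-methylguanosine"
formula = "C11H15N5O5"
parent = "G"
rt_window = [6.5, 7.5]

[Am]
full_name = "2'-O-methyladenosine"
formula = "C11H15N5O4"
parent = "A"
two_prime_methyl = true
rt_window = [11.0, 12.0]

[m1A]
full_name = "1-methyladenosine"
formula = "C11H15N5O4"
parent = "A"
rt_window = [4.0, 5.0]

[m62A]
full_name = "N6,N6-dimethyladenosine"
formula = "C12H17N5O4"
parent = "A"
rt_window = [14.5, 15.5]

[I]
full_name = "inosine"
formula = "C10H12N4O5"
parent = "A"
rt_window = [6.0, 7.0]

[m5U]
full_name = "5-methyluridine"
formula = "C10H14N2O6"
parent = "U"
rt_window = [7.0, 8.0]

[Y]
full_name = "pseudouridine"
formula = "C9H12N2O6"
parent = "U"
c_glycoside = true
rt_window = [1.8, 2.8]

[Um]
full_name = "2'-O-methyluridine"
formula = "C10H14N2O6"
parent = "U"
two_prime_methyl = true
rt_window = [7.2, 8.2]

[Gm]
full_name = "2'-O-methylguanosine"
formula = "C11H15N5O5"
parent = "G"
two_prime_methyl = true
rt_window = [8.5, 9.5]

[m6A]
full_name = "N6-methyladenosine"
formula = "C11H15N5O4"
parent = "A"
rt_window = [12.5, 13.5]

[D]
full_name = "dihydrouridine"
formula = "C9H14N2O6"
parent = "U"
no_external_calibration = true
rt_window = [2.2, 3.2]

[m3C]
full_name = "3-methylcytidine"
formula = "C10H15N3O5"
parent = "C"
no_external_calibration = true
rt_window = [4.8, 5.8]

[m2A]
full_name = "2-methyladenosine"
formula = "C11H15N5O4"
parent = "A"
no_external_calibration = true
rt_window = [10.5, 11.5]

[m1G]
full_name = "1-methylguanosine"
formula = "C11H15N5O5"
parent = "G"
no_external_calibration = true
rt_window = [8.0, 9.0]

[m2G]
full_name = "2-methylguanosine"
formula = "C11H15N5O5"
parent = "G"
no_external_calibration = true
rt_window = [9.8, 10.8]
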