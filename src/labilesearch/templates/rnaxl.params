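# 4-thiouridine RNA-crosslink workflow: nucleoside (+226.0594) and base-only
# (+94.0168) adducts searched as offsets on any residue; the base mass also
# appears as a fragment remainder of the nucleoside adduct.
mode = labile
precursor_tol_ppm = 20
fragment_tol_ppm = 10
series = by
missed_cleavages = 2
enzyme = strict-trypsin
max_variable_mods = 3
fixed_mods = C:57.02146:carbamidomethyl:5

[labile_mod]
label = 4SU-nucleoside
offset = 226.0594
residues = *
max_per_peptide = 1
fragment_remainders = 94.0168

[labile_mod]
label = 4SU-base
offset = 94.0168
residues = *
max_per_peptide = 1
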