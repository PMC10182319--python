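# Labile phosphorylation workflow (HCD phosphoproteomics).
# Phosphate is searched as a site-free mass offset with the phosphoric-acid
# neutral-loss fragment remainder for localization.
mode = hybrid
precursor_tol_ppm = 20
fragment_tol_ppm = 10
series = by
missed_cleavages = 2
enzyme = strict-trypsin
max_variable_mods = 3
fixed_mods = C:57.02146:carbamidomethyl:5

[labile_mod]
label = phospho
offset = 79.96633
residues = STY
max_per_peptide = 3
# no diagnostic or peptide remainder ions for phospho
fragment_remainders = -18.01056
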