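# Labile ADP-ribosylation workflow (HCD; use series = bycz for AIETD).
# Adenine-derived diagnostic ions gate the offset search; ribose-derived
# peptide remainder ions contribute score evidence.
mode = labile
precursor_tol_ppm = 20
fragment_tol_ppm = 10
series = by
missed_cleavages = 3
enzyme = strict-trypsin
max_variable_mods = 3
fixed_mods = C:57.02146:carbamidomethyl:5

[labile_mod]
label = ADPR
offset = 541.06111
residues = SRKDE
max_per_peptide = 1
diagnostic_mzs = 136.06232,250.09401,348.07036,428.03669
diagnostic_min_intensity = 20
peptide_remainders = 114.03169,193.99802,291.97492,406.00661
# for Arg-linked material add: fragment_remainders = -42.0205
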