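# labilesearch

A tandem-MS database search engine for **labile post-translational
modifications** — modifications that fully or partly dissociate from the
peptide during collisional activation (phosphorylation, ADP-ribosylation,
nucleoside crosslinks, …) — together with a synthetic-spectrum simulator
that makes every search behavior testable without external data.

## What it does

* **Mass-offset (labile) search**: candidate peptides may differ from the
  observed precursor by a configured modification mass (or a multiple of
  it); backbone fragments are searched *without* the modification.
* **Diagnostic-ion gating**: offset candidates are considered only for
  spectra whose summed intensity at configured diagnostic m/z values
  exceeds a threshold; all other spectra are searched at zero offset only.
* **Remainder-ion evidence**: intact-peptide ions carrying a partial
  modification (peptide remainders) add intensity to the score; backbone
  fragments retaining a partial modification (fragment remainders, possibly
  negative, e.g. −18.01056 after phosphoric-acid loss) are scored per
  candidate site and used for **site localization**.
* **Nonlabile / labile / hybrid competition**: the same modification can be
  modeled as a site-placed variable modification, a site-free offset, or
  both at once; the highest hyperscore wins.
* **Target-decoy FDR**: reversed-protein decoys, concatenated q-values,
  PSM- and peptide-level filtering, TSV reporting.
* **Simulator**: tunable lability, remainder-ion yield, diagnostic-ion
  emission, detection efficiency, noise and m/z jitter, with aligned
  ground-truth tables.

## Layout

| module | role |
| --- | --- |
| `labilesearch.chemmass` | element/residue monoisotopic masses, compositions, m/z conventions |
| `labilesearch.spectra_io` | MGF/mzML reading, MGF writing, neutral-loss removal, deisotoping, preprocessing |
| `labilesearch.protein_db` | FASTA, strict-trypsin digestion, decoys, mod-form enumeration, mass index |
| `labilesearch.fragments` | b/y/c/z ion generation, remainder variants, peptide-remainder m/z |
| `labilesearch.search_engine` | gating, candidate selection, hyperscore, mode competition, localization |
| `labilesearch.fdr_report` | q-values, FDR filtering, PSM table |
| `labilesearch.simulate` | synthetic spectra + ground truth |
| `labilesearch.cli` | `labilesearch search/simulate/benchmark`, config format, workflow templates |

## CLI

Workflow templates for the three shipped case studies (labile
phosphorylation, ADP-ribosylation, 4SU RNA crosslinks) live in
`src/labilesearch/templates/`.

```sh
# generate a synthetic dataset (MGF + truth TSV)
labilesearch simulate --config my.params --out simout --seed 1

# search spectra against a FASTA database (decoys added automatically)
labilesearch search --config src/labilesearch/templates/phospho.params \
    --spectra simout/simulated.mgf --fasta proteins.fasta --out searchout

# score a report against simulator ground truth
labilesearch benchmark --truth simout/truth.tsv \
    --report searchout/psms_filtered.tsv --out metrics.tsv
```

Configs are flat `key = value` files with repeatable `[labile_mod]` blocks
(offset mass, allowed residues, diagnostic ions + threshold, peptide and
fragment remainder masses) and an optional `[simulation]` block.

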