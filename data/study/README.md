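# Study-system inputs

`gammast_published.tsv` is the published pairwise γ_ST matrix for the five
surveyed native-forest patches (FR1–FR5) of the Valdivian-rainforest study
system this package re-analyses. It is the only study input that exists in
printed form; everything else was deposited as supplementary material and
must be placed here by hand to run the full study-data reproduction:

| file               | content                                            |
|--------------------|----------------------------------------------------|
| `sequences.fasta`  | the 73 aligned HVI control-region sequences (527 bp; GenBank accessions in the study's supplementary sample table) |
| `labels.tsv`       | `id  patch  lon  lat` per sequence (patch georeferences from the supplementary coordinates file) |
| `landscape.asc`    | the five-class land-use raster, converted from the deposited native-R grid to ESRI ASCII (`gdal_translate -of AAIGrid`) |
| `conductance.json` | class → conductance mapping (not published; a calibration input) |

When these files are present, `tests/test_acceptance.py` and
`analysis/05_study_reproduction.py` recompute the published diversity and
differentiation tables and the three Mantel correlations from them.
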