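# Reference count tables

To reproduce the original soil study's numbers, place its supplementary
per-sample count tables here, converted to the combined-table TSV dialect
of `mipner.report_io.write_table`:

- `species_counts.tsv` — species-rank counts, all six conditions x 3 replicates
- `genus_counts.tsv` — genus-rank counts, same samples

Column layout: `name`, `taxid`, `rank`, `domain`, then one column per
sample headed `sample_id|CONDITION|replicate`. The tests in
`tests/test_acceptance.py::TestReferenceStudy` consume these files; they
fail with a pointer to this note while the files are absent.
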