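# Search-engine export dialect registry.
#
# Each dialect maps the four canonical fields (identifier, spectral_count,
# score, molecular_weight) to the column names of one engine's protein-level
# CSV export. Detection is by case-insensitive presence of every mapped
# column in the header. `score_better` says which direction of the score
# scale is better, used when merging duplicate identifier rows.
# Unknown extra columns are ignored at parse time.

gpm_xtandem:
  columns:
    identifier: "accession"
    spectral_count: "total"
    score: "log(e)"
    molecular_weight: "mr"
  score_better: low        # log(e) expectation scores: more negative is better

metamorpheus:
  columns:
    identifier: "protein accession"
    spectral_count: "number of psms"
    score: "protein qvalue"
    molecular_weight: "protein mass"
  score_better: low        # q-values: smaller is better

proteome_discoverer:
  columns:
    identifier: "accession"
    spectral_count: "# psms"
    score: "score"
    molecular_weight: "mw [kda]"
  score_better: high       # engine scores: larger is better
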