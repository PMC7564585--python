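# Methods

This note documents the statistical model behind `spcquant`, the defaults
and why they were chosen, the synthetic data the tests run on, and the
numerical corner cases.

## Input model

Each input CSV is one replicate's protein-level identification list from a
PSM search engine: an accession, a spectral count (the number of
peptide-to-spectrum matches attributed to the protein), an engine score,
and a molecular weight. Column names differ by engine, so a dialect
registry (`dialects.yaml`) maps each supported export format onto those
four canonical fields; detection is by case-insensitive presence of the
full column signature, and unknown extra columns are ignored. Molecular
weight is accepted in whatever unit the file uses — it serves only as a
relative length proxy and NSAF is invariant to a global unit factor.
Duplicate accessions within one file (e.g. one row per protein-group
member) are merged by summing counts and keeping the best score, where
"best" follows the registry's score direction (log-expectation and
q-value scales: lower; Proteome Discoverer scores: higher). Rows with a
missing or non-positive molecular weight are unusable for NSAF and are
dropped with a warning.

## Stringency filtering

Replicates of a state are outer-collated into a protein × replicate count
matrix; absence is a zero count. The high-stringency set of the state is
defined by two rules evaluated per state: presence in every replicate,
and replicate-summed count ≥ `min_summed_count` (default **5**, the
conventional working value for this filter). The experiment-wide
high-stringency inventory is the union of the per-state sets ("present in
all replicates of at least one state"). Raising the threshold can only
shrink the sets (monotonicity is property-tested). Fewer than three
replicates triggers a warning, not an error: the rule is well defined for
any n, but reproducibility filtering is weak below three.

## NSAF and the pseudocount

NSAF_k = (SpC_k/L_k) / Σ_j (SpC_j/L_j), with the denominator always taken
over the state's **full unfiltered inventory** for that replicate.
Normalising before filtering keeps values identical between the
high-stringency and All Proteins output streams and preserves the
within-replicate sum-to-one property (tested at 1e-9). Zero-count cells
receive an additive pseudocount (default **0.5** spectral counts) in the
numerator only: observed proteins keep their exact abundance fractions,
while unobserved ones get a small positive value so lnNSAF — and hence
t-tests and PCA — are defined for proteins missing from some replicates.
0.5 is the customary half-count used for log-transformed count data; it
is configurable, and setting it to 0 turns missing values into hard
errors at the log step.

## Differential testing and classification

Tests run on lnNSAF (natural log), which stabilises the strongly
right-skewed NSAF scale; fold changes are reported as log2 of the ratio
of group mean NSAF, signed so positive = up in treatment. The test is the
two-sided two-sample Students t-test with pooled variance; Welch is not
the default because equal-variance pooling is the convention this
workflow family uses, and group sizes are equal in the designed use.
Degenerate zero-variance cases return p = 1 (equal means — no evidence)
or the limiting p = 0 (unequal means), logged.

A protein qualifies as *shared-for-testing* when it is high-stringency in
at least one state and observed at any stringency in both; it is *unique*
to a state only when entirely absent from the other state's unfiltered
list. This makes "unique" mean genuinely unobserved while borderline
proteins still get a test, and it reduces to plain set intersection when
the unfiltered and filtered lists coincide. The All Proteins stream tests
the full union of both states' inventories (the pseudocount completes the
vectors) and has no unique category. Classification is p < alpha
(default 0.05, no fold-change gate) for the standard stream, or
BH-adjusted q ≤ Q\* for the refined stream once a same-same threshold Q\*
exists.

## Same-same analysis

For a six-replicate state, the ten non-redundant 3-vs-3 partitions are
enumerated canonically (lowest replicate number fixed in group A; the
general C(2k,k)/2 helper is brute-force-checked for k ≤ 4). Within each
partition the state's high-stringency proteins (MSC over all six
replicates — stricter and partition-independent, rather than per-triplet)
are tested group A vs group B, BH-adjusted, and counted at each Q of a
0…1 grid in 0.01 steps: PQ-FDR(q) = 100 × #(q_value ≤ q)/n. Curves are
averaged per state, then across the states that have six replicates, and
the threshold Q\* is the largest grid point with grand-average PQ-FDR at
or below the target (default **1%**), refined by linear interpolation
between the bracketing grid points — the published thresholds of this
procedure are not multiples of 0.01, so sub-grid refinement is clearly
intended. If even the first grid point exceeds the target, Q\* = 0 with a
warning (no permissive threshold exists). The derived Q\* then replaces
0.05 in a re-classification of every pairwise comparison.

## Synthetic data

The generator emulates the input contract end to end: per-protein mean
abundances are log-normal across the proteome (median ≈ 10 SpC, ln-sd 1 —
a realistic two-orders-of-magnitude dynamic range for the quantifiable
fraction), per-replicate counts are negative binomial with dispersion 0.3
(var = μ + 0.3μ², the over-dispersion typical of biological replicates;
Poisson is the clean-null option used for calibration checks), a 5%
per-replicate dropout deletes the protein's row entirely, and planted
differential expression multiplies 20% of proteins four-fold (half up,
half down) in every non-control state. Scores are nominal draws that
merely populate the column. Everything is a deterministic function of the
seed; files are byte-identical across runs.

What the generator does **not** emulate: peptide-level effects (shared
peptides, protein grouping), correlated dropout at low abundance,
batch/run-order drift, and realistic score distributions. Passing tests
therefore demonstrate the correctness and calibration of the statistical
machinery on data matching its assumptions, not the end-to-end behaviour
of any particular search engine's output on real tissue.

## Test and calibration problem sizes

The statistical checks run on 200-protein, six-plus-six-replicate
simulations: 50 Monte-Carlo null repeats for the false-positive-rate
check (clean-null configuration, pooled binomial tolerance), 25 for the
held-out threshold calibration, and 3 repeats for the planted-DE recovery
guard, which is evaluated on the pipeline's final six-replicate output —
the refined classification at the derived Q\* — counting a planted
protein as recovered when it lands in the correct directional category
(including the unique category when the four-fold shift removes it from
one state entirely).

## Numerical choices and edge cases

- p-values are floored at machine epsilon only for volcano plotting.
- Heatmap ranking: ascending p, ties by descending |log2 FC|, then
  identifier — fully deterministic.
- The proportional Venn solves the two-circle lens-area equation with
  Brent's method; with only two sets an exact-area layout always exists.
- PCA treats replicates as observations and proteins as variables,
  protein-centred and unscaled (replicate-level QC is the purpose).
- Output CSVs are identifier-sorted with replicate-ascending columns, and
  the zip archive uses fixed timestamps, so identical inputs give
  byte-identical bundles.
- More than two states are compared pairwise against the control (the
  first state supplied, or `--control`).

## Known limitations

- No peptide-to-protein inference or shared/distributed NSAF; each input
  row is taken as one protein identifier.
- No moderated-variance statistics or missing-value imputation beyond the
  pseudocount.
- Mixed-stringency qualification (passing one MSC rule but not the other)
  is not offered; such proteins appear only in the All Proteins stream.
- With asymmetric replicate counts, only states with exactly six
  replicates contribute same-same curves.
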