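# geneburden

Case-control rare-variant analysis as a reusable pipeline: qualifying-variant
filtering, per-gene collapsing burden testing against a control cohort,
per-individual mutational-burden comparison, and multi-gene (oligogenic)
carrier enrichment — plus a synthetic-cohort simulator so every stage can be
calibrated and tested without external data.

## What it does

1. **Qualifying-variant filter** (`geneburden.qualifying_filter`): keeps
   variants that are rare both internally (folded minor-allele frequency in
   the combined case+control cohort, default < 0.001) and externally
   (maximum AF over reference populations such as ExAC/gnomAD, default
   < 0.001), have a coding/splice consequence (synonymous included by
   default), and optionally fall in a gene panel. Every rejection is
   audited with the criterion that failed.
2. **Known-gene screen**: reports qualifying case variants in a panel of
   previously reported causal genes.
3. **Burden scan** (`geneburden.burden_stats`): per panel gene, a 2x2
   carrier table (case carriers vs. non-carriers against controls) tested
   with both the Pearson chi-square (no continuity correction, 1 df,
   upper tail via `erfc`) and Fisher's exact test (one-sided enrichment and
   two-sided, log-factorial accumulation). Genes are ranked by the
   chi-square p-value; zero-carrier genes stay in the output with p = 1.
4. **Per-individual burden**: distinct-variant and allele counts per
   individual, compared between groups with a one-tailed pooled t-test.
5. **Oligogenic analysis** (`geneburden.oligogenic_analysis`): individuals
   whose qualifying variants span >= 2 distinct panel genes, with the same
   2x2 kernel applied to multi-gene carrier counts.
6. **Simulator** (`geneburden.synthetic_cohort`): cohorts with known
   per-gene carrier probabilities and odds-scaled case enrichment, plus
   type-I-error and power/odds-ratio-recovery experiments that run the full
   pipeline per replicate.

A packaged reference cohort (`build_reference_cohort`) encodes a published
37-case / 534-control study's summary tables (per-gene carrier counts,
per-patient multi-gene combinations, known-gene screen hits), so the
pipeline's expected output is known exactly; the packaged 96-gene candidate
panel and 5-gene known panel live in `src/geneburden/data/`.

## CLI

```bash
geneburden run-all --fixtures --seed 1 --out results/run    # full pipeline on the packaged cohort
geneburden fixtures --seed 1 --out results/fix              # emit the packaged cohort as TSVs
geneburden filter --variants v.tsv --roster r.tsv --out results/filtered
geneburden burden --in results/filtered --out results/burden
geneburden oligogenic --in results/filtered --out results/oligo
geneburden simulate --seed 7 --gene BAZ1B:0.002:10 --gene SUFU:0.002 --out results/sim
geneburden calibrate --seed 7 --n-reps 500 --out results/cal
```

Inputs are plain TSVs (annotated variant table + individual roster) or a
VCF with a sidecar annotation TSV; gene panels are one symbol per line.
Every subcommand writes a `manifest.json` (config echo, seed, input
checksums) and timestamp-free result files, so re-runs are byte-identical.
Exit codes: 0 success, 2 validation/usage error, 1 runtime error.

## Notes on the statistics

Both tests are always reported side by side: the asymptotic chi-square can
be anti-conservative on sparse tables, while one-sided Fisher is
conservative (verified by the packaged calibration experiment). The
one-sided Fisher alternative is carrier *enrichment* in cases,
P(X >= a) under the hypergeometric model conditioning on all margins; the
two-sided p sums all tables whose point probability does not exceed the
observed one. `tests/oracles.py` holds an exact-rational enumeration oracle
against which the kernel is verified for every table with N <= 40.
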