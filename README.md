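# xciskew

Calling skewed X-chromosome inactivation (XCI) from standard NGS data.

In females, one X chromosome is epigenetically silenced in each cell.
Usually the choice is close to random across the cell population
(~50:50), but in some individuals one parental X is preferentially
inactivated — *skewed XCI* — which can unmask or modify X-linked disease.
`xciskew` detects skew directly from exome + RNA-seq data that rare-disease
clinics already generate, without the focal clinical AR methylation assay:
at every exome-confirmed heterozygous site on X, the RNA-seq
reference/alternate read counts reveal whether one allele dominates
expression, and a sample whose sites are biased chromosome-wide relative
to a healthy reference population is called skewed.

Intended users: bioinformaticians in clinical genomics / transcriptomics
groups working with female cohorts (bulk RNA-seq from blood or other
tissue) who need a per-sample skewed/random XCI status.

## Model

For heterozygous site *i*, let *r<sub>ji</sub>* and *a<sub>ji</sub>* be the
RNA reads supporting the reference and alternate allele in sample *j*
(the CVAC, computed variant allele counts). Across a healthy reference
cohort the reference-allele count at depth *n* is modelled beta-binomially,

&nbsp;&nbsp;*x* ~ BB(*n*, μ, σ),&nbsp;&nbsp; α = μ/σ,&nbsp; β = (1−μ)/σ,

where μ is the mean reference fraction and σ the between-sample
overdispersion (σ→0 recovers the binomial). Laplace smoothing (+*k* to
each allele) regularizes the cohort counts before fitting. Three nested
nulls are fitted by maximum likelihood: per position (sites with ≥3 reads
in ≥10 samples), per gene (pooled across the gene under the same rule),
and one global model on count pairs pooled from 2000 randomly sampled
positions.

A patient site with depth > 10 is scored against the most specific
available null (position → gene → global) with a two-sided p-value
p = min(1, 2·min(P(X ≤ x), P(X ≥ x))); the patient's counts are not
smoothed. The per-sample statistic is the percentage of tested sites with
p < 0.05, and a sample is *skewed* when that percentage exceeds a
threshold — 14% by default, or derived per cohort as a local minimum of
the density of per-sample percentages constrained to an expected
population skew rate of 10–20%.

## Worked example

Everything below is runnable offline: the `simulate` subcommand generates
a synthetic female cohort with known XCI ratios, including VCF/mpileup
fixtures for the extraction stage.

```sh
# 1. a 135-sample reference cohort (90% random XCI) sharing one site map
xci simulate --n-samples 135 --n-sites 150 --seed 42 -o cohort
# 2. fit the three-tier beta-binomial reference model
xci build-ref --cvac-dir cohort/cvac --seed 7 -o model.json
# 3. a strongly skewed patient (rho = 0.9) with raw-format fixtures
xci simulate --n-samples 1 --n-sites 150 --seed 42 --fixtures -o patient
# 4. extract CVAC from its VCF + mpileup (PAR-excluded, coding-restricted)
xci extract-cvac --vcf patient/fixtures/sample.vcf \
    --mpileup patient/fixtures/sample.mpileup --sample S0000 \
    --par patient/fixtures/par.bed --coding patient/fixtures/coding.bed \
    --genes patient/fixtures/genes.bed -o patient.cvac.tsv
# 5. score the patient and classify
xci call-skew --cvac patient.cvac.tsv --model model.json \
    --escape patient/fixtures/escape.bed -o calls
xci classify --summaries calls --threshold 14 -o report
```

Output printed by the commands above:

```
simulated 135 samples x 150 sites -> cohort
fitted 150 position models, 30 gene models and 1 global model -> model.json
wrote 150 CVAC records to patient.cvac.tsv
S0000: 110/149 sites significant (73.83%)
1/1 samples called skewed at 14.00% threshold
```

Reading: of the patient's 150 sites, 149 had RNA depth > 10 and were
tested; 110 (73.83%) deviated significantly from the healthy-cohort null,
far above the 14% threshold, so the sample is called skewed — consistent
with its simulated XCI ratio of 90:10. The per-site table
(`calls/S0000.sites.tsv`) records each p-value and which model tier
scored it; the summary also reports the percentage recomputed without
escape-gene sites (80.73% here — escape sites stay biallelic even under
skew, so excluding them sharpens the signal).

The clinical comparator is available as a convenience:
`xci concordance --calls <csv>` builds the NGS-vs-assay confusion matrix
with percent positive agreement and its exact (Clopper–Pearson) 95% CI.

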