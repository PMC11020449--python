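# Methods

## The statistical model

Allelic expression at a heterozygous X-linked site varies between healthy
females for two reasons: binomial sampling of reads at finite depth, and
genuine between-individual variation in XCI ratio. A binomial null would
ignore the second source, so reference counts are modelled beta-binomially:
the latent per-individual reference-allele fraction is Beta(α, β) with
α = μ/σ and β = (1−μ)/σ, giving mean μ and a dispersion σ whose intraclass
correlation is σ/(1+σ). This mean/dispersion parameterization (the GAMLSS
"BB" convention) is used everywhere, recorded in the model file, and
exposed on `BetaBinParams` (`.alpha`/`.beta` give the shape view).

Fitting is maximum likelihood over (logit μ, log σ) with L-BFGS-B from a
method-of-moments start (pooled fraction for μ; excess variance of
per-pair fractions for σ), with a Nelder–Mead retry if the gradient path
stalls. μ is clamped to (1e−6, 1−1e−6) and σ to (1e−8, 1e3); a perfectly
binomial sample drives σ to its lower bound, which is the correct
boundary solution. The optimizer is required never to end below the
moment start's likelihood; that invariant is tested.

Reference counts are Laplace-smoothed (+k to each allele, default k = 1)
before fitting. Smoothing is regularization of the *null*, motivated by
low/zero counts in cohort data; patient counts under test are never
smoothed. k = 1 is the conventional add-one choice; it is configurable
(`--smooth`).

## The three model tiers and their eligibility

* **Position models** — one fit per site covered by ≥ `min_reads` (3) RNA
  reads in ≥ `min_samples` (10) cohort samples, on exactly those samples'
  pairs. Both bounds are inclusive, and low-depth samples neither count
  toward eligibility nor enter the fit.
* **Gene models** — per gene, pooling all (position, sample) pairs with
  depth ≥ `min_reads`; the pooled observation count must reach
  `min_samples`. The depth/sample rule applied to pooled observations is
  this package's reading of "same criteria as the position model" at gene
  level (3 positions × 5 samples = 15 observations qualifies).
* **Global model** — 2000 distinct positions sampled without replacement
  (seeded; positions are sorted before sampling so the draw is
  reproducible across platforms), pairs pooled unweighted. Cohorts with
  fewer positions use all of them with a warning.

Patient sites are always scored by the most specific available tier
(position → gene → global); a site seen in the cohort but below
eligibility still falls to the gene or global tier — near-eligible
positions get no special treatment.

## The outlier test

For a patient site with total depth n > 10 (strict, both for the DNA
depth filter in extraction and the RNA depth filter here), the tested
statistic is the reference-allele count x; the two-sided p-value is the
doubled minimum tail, point mass included, capped at one:
p = min(1, 2·min(P(X ≤ x), P(X ≥ x))). Because the test is two-sided the
choice of reference vs alternate allele is inconsequential; it is fixed
to reference and documented. An alternative construction — the
"minimum-likelihood" method, p = P(pmf(X) ≤ pmf(x)) — is available via
`method="minlike"` for sensitivity analyses. No multiple-testing
correction is applied: the per-sample statistic is deliberately the raw
fraction of sites with p < α, a summary whose meaning depends on using
the uncorrected per-site level.

Both constructions are *exact* discrete tests, hence conservative: the
achieved size at nominal α = 0.05 is below 0.05 and depends on depth
(roughly 0.032–0.043 for depths 20–100, approaching ~0.048 only at depth
≥ 400). This conservatism is a property of doubling an inclusive tail on
a lattice, not an implementation artifact; the validity bound
P(p < α) ≤ α is what the test suite asserts as an invariant. Consumers
comparing percentages across samples are unaffected (all samples share
the same conservatism), but the fraction of significant sites in a truly
null sample should be expected near 0.04, not 0.05, at typical depths.

## Extraction choices

* VCF: heterozygous means exactly one reference plus one alternate allele
  after decomposing multi-allelic records; SNVs and 1-bp indels only;
  FILTER must be PASS ('.' counts as PASS by default, rejected in strict
  mode); DNA depth strictly > 10; GQ ≥ 20. Records missing GQ/DP are
  skipped with a warning.
* PAR exclusion defaults to GRCh37/hg19 PAR1 X:60,001–2,699,520 and PAR2
  X:154,931,044–155,260,560 (1-based inclusive as published), overridable
  with any BED.
* Coordinates: positions are 1-based internally and in VCF; all BED I/O
  is 0-based half-open. Chromosome aliases ("chrX", "23") normalize to
  "X".
* Pileup counting enforces the base-quality floor (default Q30) only;
  mapping-quality filtering belongs to the pileup producer (`samtools
  mpileup -q 20`). Read-start mapping-quality characters, read ends and
  reference skips are consumed per the pileup grammar; `N` and deletion
  placeholders count toward neither allele. 1-bp indel alleles are
  counted from `+1X`/`−1X` tokens anchored on a reference-matching base,
  gated by the anchor's quality — the attribution of indel reads to
  alleles is this package's documented choice, since pileup text has no
  canonical convention for it.
* Overlapping gene annotations resolve to the first interval by
  (start, end, name); intergenic sites carry a sentinel and are excluded
  from gene models only.

## Threshold derivation and classification

A sample is skewed iff its percentage of significant sites strictly
exceeds the threshold. The default fixed threshold is 14%, appropriate
when patients are scored against a healthy reference cohort; cohorts
modelled against themselves tend to sit lower (a 12% preset fits that
design), and users are advised to re-derive per cohort. Density mode
needs ≥ 20 spread-out samples: a Gaussian KDE (Silverman bandwidth, 512
grid points over [0, max+5]) is scanned for interior local minima inside
the search range (default 5–25%); among candidates whose implied call
rate lies in the expected population rate (default 10–20%) the deepest
minimum (lowest density) is chosen — a tie-break this package fixes —
otherwise the candidate closest to that rate window; with no candidates
the fixed value is used with a warning.

Concordance against the clinical AR assay collapses high/moderate skew
to one "skewed" class, drops uninformative assay results from the
denominator, and reports percent positive agreement with the exact
Clopper–Pearson 95% CI (for 9/10 agreement: 0.5550–0.9975; a published
two-decimal upper bound of 0.99 for this case reflects truncation, not a
different interval).

## The synthetic cohort generator

The generator collapses cellular XCI mosaicism to a site-level law: a
sample with XCI ratio ρ ∈ [0.5, 1] has expected reference fraction ρ or
1−ρ at each site, with a fair phase coin per site (the data are
unphased), except escape sites, which sit at 0.5 regardless of ρ. Counts
are beta-binomial around that expectation with site-level dispersion
σ_site (default 0.02 — sequencing-scale noise, far smaller than the
between-individual dispersion the reference model estimates); depths are
negative binomial (mean 50, dispersion 5, capped at 500), typical of
well-covered coding sites in blood RNA-seq. Reference cohorts draw ρ from
a 90%/10% mixture — U(0.5, 0.65) for random XCI, U(0.85, 0.99) for
skewed — matching the ~10% population prevalence of skew; escape sites
default to 5% of sites (a minority of sampled coding het sites escape
silencing even though a larger share of X-linked genes can). The
emulation is deliberately idealized: no allelic mapping bias toward the
reference genome, no genotyping error, no expression-level variation
between genes, and identical site coverage across samples. Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated model, not robustness to alignment artifacts — the escape/editing
site exclusion hooks and the per-cohort threshold guidance are the
intended mitigations on real data.

All randomness flows from one spec seed through named child streams
(sample index, site map), so any sample regenerates independently and
byte-identically.

## Problem sizes used in validation

The bundled studies run at: 135 reference samples × 150 shared sites
(mirroring the reference-cohort scale the method targets, with a site
count that keeps every tier exercised); 20 synthetic patients per
replicate and 20 replicates for end-to-end recovery; 10,000 null sites
for calibration; 200 pairs × depth 50 × 20 replicates for μ recovery.
These sizes give Monte-Carlo standard errors comfortably below the
assertion tolerances while keeping the full validation under a minute.

## Known limitations

* The exact-test conservatism above: per-site significance rates under
  the null land near 0.04 at typical depths, not the nominal 0.05.
* Tissue is whatever the RNA-seq came from; XCI skew is tissue-variable
  and a blood-derived call need not transfer.
* The method is unphased by design: it detects biased expression, not
  parental origin.
* Gene-model eligibility on pooled observations can admit genes whose
  individual positions are all below the position rule; this matches the
  pooling construction but means gene and position tiers are not nested.
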