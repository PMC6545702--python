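# Methods

## The screen

**Binning.** CpG calls (forward-strand position, methylated/total read
counts) are reduced to fixed 100-bp bins: bin start = ⌊pos/100⌋·100,
bin methylation = 100·Σn_meth/Σn_total over the bin's CpGs. Read-weighting
(rather than averaging per-CpG fractions) makes binning and read-pooling
commute, so "pool each individual's reads across tissues, then bin" and
"bin, then pool counts" are the same operation. Reverse-strand calls at
pos+1 are merged into the forward-strand record (CpG methylation is
strand-symmetric). Sex chromosomes are excluded by default; a cohort of 10
is far too small to separate X-inactivation mosaicism from systemic
variation.

**Informative bins.** A bin enters the screen iff it contains ≥ 1 covered
CpG and every individual has pooled depth ≥ 10 reads (`min_depth` and the
required fraction of individuals are configurable). The all-individuals
default is deliberate: a 10-point interindividual correlation with missing
points is not worth screening.

**Region construction.** Per chromosome, a greedy left-to-right scan joins
adjacent informative bins: a candidate bin extends the open region iff the
genomic gap to the previous member is ≤ `max_gap_bp` (default 0, i.e.
strictly adjacent bins) and the Pearson R between the candidate's pooled
per-individual profile and the running region-*mean* profile is ≥ 0.71.
Correlating against the region mean rather than only the previous bin
stabilizes chains against a single noisy bin. Regions need ≥ 2 bins — one
bin is not a region. Anti-correlated neighbours are never joined; distant
anti-correlated regions remain separate calls by design.

**ITC screen and filters.** Region-average methylation per (individual,
tissue) is read-weighted over member bins. One Pearson R per unordered
tissue pair across individuals; the region is systemic iff the minimum over
pairs is ≥ 0.71. All thresholds are inclusive. Final calls additionally
need ≥ 5 distinct covered CpGs and an interindividual range (max − min of
pooled region methylation) ≥ 20 pp. The IIR is computed on pooled (not
per-tissue) methylation: pooling is what the region construction saw, and
it is the stabler estimate at 3× the depth.

**Permutation null.** Subject labels are shuffled independently within each
tissue — destroying the individual linkage that systemic variation creates
while preserving every tissue's marginal — and a fixed number of regions is
resampled per permutation (defaults: 2000 permutations × 1000 blocks for
desk-scale work; the region-tissue mean tensor makes each permutation a
handful of vectorized correlations). The identity permutation is redrawn,
never counted. Per-region p = (1 + #{null ≥ obs}) / (1 + N), the add-one
estimator, which is a valid permutation p and never zero. `chance_rate(τ)`
is the fraction of null *draws* (blocks sampled with replacement) at or
above τ; it is reported alongside the draw count so a unique-region rate
can be derived if wanted.

**Clustering QC.** Average-linkage hierarchical clustering of samples on
1 − Pearson R between methylation vectors (bins with any missing value
dropped). On all informative bins samples should cluster by tissue; on
systemic bins, by individual — the screen's qualitative signature.

## Genetics

* **mQTL** — OLS of pooled region methylation (%) on additive genotype for
  every SNV within 10 kb of the region boundary; SNVs whose cohort
  genotypes do not include all of {0, 1, 2} are excluded (a 2-level dosage
  in 10 individuals is too easily confounded). Benjamini–Hochberg is
  applied across the full region × SNV table; a region is positive when its
  best SNV has |β| ≥ 10 pp/allele, R² ≥ 0.5 and q < 0.05. |β| is used
  because allele labelling makes the slope sign arbitrary. Regions with no
  testable SNV are *non-informative*, distinct from negative.
* **Pairwise donor concordance** — for each of the 45 donor pairs, across
  regions: |Δ mean window genotype| vs |Δ pooled methylation|; the per-pair
  R² distribution summarizes how much interindividual methylation variation
  tracks cis genotype. Absolute differences are used on both axes since the
  pairs are unordered.
* **Read-depth check** — Spearman correlation of per-individual mean region
  depth vs pooled methylation; a CNV that removes one allele halves depth
  and shifts methylation, so a significant association flags copy-number
  artefacts. Constant depth returns NA. The p-value uses the standard
  t approximation.
* **Decay comparison** — squared methylation correlation for all
  (inside-bin, flanking-bin) pairs and composite LD r² (squared genotype
  dosage correlation) for all (inside-SNV, flanking-SNV) pairs within
  ±20 kb of the region boundary (distance of exactly 20 kb included),
  averaged in 1-kb distance bins; Spearman correlation between the two
  binned profiles separates haplotype-driven regions (both decay together)
  from pure epigenetic variation (methylation structure without LD
  structure). The Spearman p uses the t approximation over ~20 distance
  bins; its null is calibrated to the 5% level (tail accuracy beyond that
  is limited by the approximation, which is the standard choice).

## Genomic context

Matched controls are rejection-sampled per call on the informative bin
grid: same chromosome, identical length, CpG count within ±10% of the
target, disjoint from all calls and other controls. Enrichments are 2×2
overlap tables (≥ 1 bp intersection, half-open intervals) tested by χ²
with Yates correction or Fisher's exact test; odds ratios use the Haldane
0.5 correction when a cell is zero. Subtelomeric = wholly within 5 Mb of a
chromosome end (the window is a declared default — no canonical value
exists — and is configurable). Genome-wide clustering is a one-sample KS
test of region midpoints on the concatenated, normalized genome coordinate.
superCoRSIVs are same-chromosome call pairs with pooled-methylation R ≥
0.71 across a gap ≥ 50 kb (beyond typical haplotype-block scale), clustered
by single linkage; the TAD test compares, per TAD set, the proportion of
spans wholly inside a single TAD against matched controls with a paired
t-test across TAD sets.

## Cohort analyses

**Seasonality.** Per site, OLS of methylation on {sin, cos}(2πkd/365.25),
k ≤ harmonics (default 1; the leap day is handled by the fractional period,
not calendar logic). The harmonic terms are F-tested jointly against the
intercept-only model; amplitude = √(a²+b²) pp and peak day =
(365.25/2π)·atan2(a, b) mod 365.25, so a pure positive cosine peaks at
day 0. BH across sites at FDR 20%. Class enrichment of seasonal
significance uses a one-sided Fisher test (class vs pooled other classes):
only an *excess* of seasonal sites counts, so a class at or below the
reference rate scores p ≈ 1 rather than flagging the depletion induced by
pooling an enriched class into the reference.

**Methylation–expression.** Spearman per (region, gene, expression tissue)
over shared subjects (≥ 8 required), BH within each tissue family;
concordance counts genes associated in the assayed tissue that are also
associated in each other tissue (raw p < 0.05, the conventional screen
level for this analysis).

## Synthetic data generator

The generator emulates the statistical structure of the reference design —
10 individuals × 3 tissues at ~40× — on a 2 × 5 Mb toy genome (100,000
bins), with planted ground truth for every pipeline stage:

* **Latent levels.** Null bins: one population level per bin, uniform on
  [10, 90]%. Systemic regions (defaults: 50 genotype-driven + 50
  stochastic, 3–10 bins long): one level per individual shared by all
  tissues. Stochastic class: uniform draws rescaled so the cohort realizes
  the planted IIR exactly (drawn uniform on [30, 70] pp). Genetic class:
  level = baseline + (IIR/2)·(g − 1) on the driver SNV's additive genotype;
  drivers are redrawn at the haplotype-block level until tri-genotypic in
  the cohort, so the realized IIR again equals the planted value and the
  mQTL three-genotype rule is satisfiable. Tissue DMRs (default 200): a
  fixed ±30 pp offset for one tissue, identical across individuals — the
  screen's principal confusable. Every bin additionally carries a
  per-(bin, tissue) landscape offset (Normal, sd 5 pp) shared by all
  individuals: tissue methylomes differ genome-wide, which is what makes
  whole-genome sample clustering group by tissue. Latent levels are clamped
  to [2, 98]%.
* **Counts.** CpGs per background bin ~ Poisson(2) (≈ 1 CpG/50 bp, a
  CpG-containing-bin rate close to genomic); planted bins are CpG-dense
  (2 + Poisson(1), so planted regions always clear the 5-CpG filter and
  match the observed 5–10+ CpGs of real calls). Per CpG and sample:
  depth ~ Poisson(40), methylated reads ~ beta-binomial with ρ = 0.05 —
  real WGBS is overdispersed, and a binomial generator would flatter the
  permutation calibration.
* **Genotypes.** SNVs every 2 kb in haplotype blocks of 30 kb; within a
  block each haplotype carries a block state that SNVs copy with
  probability 0.95 (strong within-block LD), across blocks independent.
  The *fully genetic* architecture used for the pairwise-concordance
  contrast is the idealized extreme: copy probability 1.0 and 50-kb blocks
  (the scale below which most Caucasian haplotype blocks fall), so the
  window-average genotype is a faithful proxy of the driver. The decay-
  analysis locus uses a Markov allele chain (adjacent-SNV correlation 0.9)
  so LD decays geometrically, with each bin's methylation driven by its
  nearest SNV; its LD-free counterpart draws independent SNVs and a
  stochastic region.
* **Seasonal cohort.** n = 233 subjects, conception dates uniform over the
  year; planted sites add amplitude·cos(2π(d − peak)/365.25) (defaults
  5 pp, peak day 240, noise 5 pp, 50 planted + 150 null sites).

**What the generator does not emulate** — and hence what passing tests do
not show about real data: real CpG spacing and methylation bimodality,
mappability/coverage artefacts, cell-composition heterogeneity within
tissues, trans-acting genetic effects, batch and post-mortem covariates,
and realistic LD beyond exchangeable block/chain models. The generator
demonstrates that the *algorithms* recover the structure they target under
honest noise, not that the biological discovery replicates.

## Problem sizes and numerical choices

The shipped tests and `scripts/acceptance.py` run the default cohort
(100,000 bins × 30 samples), a 2000 × 1000 permutation null, 200-replicate
recovery experiments for mQTL and seasonality, 100/200-replicate decay
experiments, and 2 × 2 Mb cohorts for the architecture contrast — sizes
chosen so the whole suite completes in minutes on one CPU while keeping
every Monte-Carlo assertion comfortably powered. Degenerate inputs are
contracts, not crashes: constant vectors give NaN correlations (regions
excluded and counted), constant depth gives NA Spearman, empty region or
feature sets raise errors, and all-degenerate permutation draws raise
rather than silently returning an empty null. Threshold comparisons are
inclusive (≥) throughout; p-value estimators are add-one; BH families are
as stated per analysis (full mQTL table; per expression tissue; across all
seasonal sites).

## Known limitations

* With 10 individuals the ITC and pairwise statistics are coarse; the
  screen's operating characteristics here describe the reference design,
  not arbitrary cohorts.
* The step-wise comparator (region mean) and gap rule (strict adjacency)
  are declared defaults; other region-building conventions exist and are
  exposed via `max_gap_bp`/`r_min`.
* The informative-depth rule (≥ 10 pooled reads in all individuals) is a
  declared default, not a canonical definition; it is configurable.
* `pairwise_geno_meth` uses absolute differences on both axes; a signed
  convention would give slightly different R².
* The subtelomeric window (5 Mb) and superCoRSIV span floor (50 kb) are
  declared assumptions, configurable at call sites.
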