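# Methods

`cnvpop` analyses a population-level *deletion* CNV call set from two cattle
breeds: a table of CNV intervals with one diploid deletion genotype per
animal (`0/0`, `0/1`, `1/1`; dosage 0/1/2 deleted alleles), a sample→breed
map, and optional gene/QTL annotation tracks.  This note records the models,
the parameters that matter, and the design decisions taken where the design
was genuinely open.

## Call-set model and conventions

* Coordinates are 1-based inclusive internally (the convention of Ensembl,
  Animal QTLdb and the genotype-table layout we consume); BED I/O converts
  to and from 0-based half-open at the boundary.  Whether the upstream
  genotype table is 0- or 1-based is not documented anywhere we could find;
  the 1-based reading is an assumption users should be aware of, and the
  `length_mode` switch (`inclusive`: end − start + 1, the default; `span`:
  end − start) exposes the one place the ambiguity is numerically visible
  (mean CNV length shifts by exactly 1 bp).
* Genotype strings are parsed strictly: `0/0`, `0/1`, `1/1`, `./.` and
  nothing else.  Silent coercion of malformed genotypes hides corruption,
  so any other token is a hard error naming the CNV and sample.
* The completeness filter keeps only CNVs genotyped in every animal; all
  downstream statistics require a complete matrix and raise otherwise.

## Gene deletion scores

Per CNV, the *deletion count* is the number of carrier individuals
(genotype `0/1` or `1/1`), range 0..N — the carrier reading is forced by
that stated range, since allele dosage would range to 2N.  An
allele-dosage mode is kept behind `score_mode="allele"` for sensitivity.
A gene's deletion score is the sum of deletion counts over all CNVs
intersecting its locus span in ≥ 1 base (whole gene span, not exon union —
deletion burden in introns counts).  A CNV spanning k genes contributes to
all k scores; no de-duplication, matching the per-gene definition.

Significance: a normal distribution is fitted to the genome-wide score
vector (sample mean, n−1 standard deviation — the estimator choice is
immaterial at the scale of a thousand genes) and each gene's p-value is the
upper-tail probability of its score.  Genes with p < α (default 0.01) are
the candidate set.  This "empirical p-value" is a distributional fit, not a
rank-based empirical probability; a rank option
(`genes.rank_tail_pvalues`) exists but is not the default, because the
normal fit is the procedure the score was designed around.

## QTL deletion density

QTL lengths vary over five orders of magnitude, so their raw deletion
scores mostly track length.  The density statistic divides it out:
*average distance between deletions* = QTL length / deletion score, in
bases per deletion.  QTL overlapping no CNV are excluded; the remaining
QTL are ranked ascending (densest first) with ties broken toward the
larger score, then lexicographic id, and the top k (default 30) reported.
No distributional significance model is applied to QTL — the density
distribution is too irregular to support one, which is exactly why the
fixed top-k report exists.

## Selection scan (Nei's F)

Per CNV and breed j, the deletion allele frequency is
p_j = (het + 2·hom) / (2 n_j).  With subpopulation weights c_j = n_j / N
(the only subpopulation sizes available; `weights="equal"` for
sensitivity):

    H_obs = Σ_j c_j · 2 p_j q_j        H_exp = 2 p̄ q̄,  p̄ = Σ_j c_j p_j
    F = (H_exp − H_obs) / H_exp

Algebraically F = Var_c(p) / (p̄ q̄), so F ∈ [0, 1] whenever H_exp > 0 —
this identity is the independent oracle the test suite checks to 1e−12.
The weighted p̄ is used (an unweighted-mean option exists) because it keeps
the estimator internally consistent and guarantees the [0, 1] range.
CNVs with H_exp = 0 (no variation anywhere) have undefined F and are
*excluded* from the significance pool rather than assigned p = 1, so they
cannot distort the fitted null.

Significance mirrors the gene-score procedure: normal fit to the defined F
vector, upper-tail p, then Benjamini–Hochberg adjustment; the selected set
is q ≤ α (default 0.01; "less than" honoured as ≤ so that exact ties at
the threshold are kept).  A within-sample rank method is implemented for
comparison, but note its structural property: rank p-values are exactly
k/m for the k-th largest F, so every BH-adjusted value equals 1 and the
rank+BH route can never call anything at any FDR below 1.  It is a
conservativeness diagnostic, not a discovery method; a unit test pins this
property down.

## Breed-specific CNVs

A putative breed-specific CNV has ≥ 1 observed deletion allele in exactly
one breed and 0 in the other — judged on observed genotypes of the sampled
animals, not on an inferred population frequency.  Confirmation requires
deletion allele frequency strictly > 0.1 in the carrier breed (alleles /
2n, the same definition the selection scan uses; a carrier-fraction mode is
available since the threshold's intended scale is not documented).  The
"nearby gene" assignment defaults to direct overlap (flank = 0) — the
restrictive default is deliberate, as permissive flanks inflate gene lists
— with `flank` configurable in bases.

## Synthetic data generator

The generator emulates the two-breed resequencing design so that every
stage has a no-download test surface with known truth:

* **Samples**: 22 + 10 animals (configurable), labels `Hanwoo`/`Holstein`.
* **CNV intervals**: ~6,811 by default, placed uniformly (chromosome chosen
  proportional to length) on a synthetic 29-autosome, 2.47 Gb genome;
  lengths log-normal with mean 2,732.2 bp (σ = 0.75 on the log scale,
  median ≈ 2.06 kb), floor 100 bp.  Real CNV placement is non-uniform
  (segmental-duplication hotspots); the generator does not model that, so
  passing tests say nothing about clustering-sensitive behaviour.
* **Genotypes**: Hardy–Weinberg within breed — dosage ~ Binomial(2, p_j)
  per animal.  HWE is the minimal standard null consistent with the
  allele-frequency definitions above; inbreeding, relatedness and linkage
  disequilibrium between CNVs are deliberately absent, so recovery results
  here are best-case relative to real pedigree-structured samples.
* **CNV classes** (fractions of n_cnvs): background CNVs share one
  frequency between breeds, drawn from Beta(0.5, 2.0) — a rare-skewed
  deletion site-frequency spectrum (mean 0.2, negligible mass at fixation)
  chosen so a default run reproduces the qualitative class structure of a
  real two-breed deletion call set (roughly 60% shared, ~2 fixed CNVs,
  several hundred confirmed breed-specific calls per the larger breed).
  `differentiated` CNVs (1.5%) get a planted between-breed gap δ = 0.6;
  `specific_b1`/`specific_b2` (11.5% / 3.3%) have frequency 0 in the other
  breed and U(0.02, 0.6) in the carrier breed, so the 0.1 confirmation
  threshold is exercised from both sides; `monomorphic` (0.03%) are fixed
  `1/1` everywhere.  Because genotypes are sampled, *realized* classes
  differ from planted labels (a low-frequency background CNV can realize
  as one-breed); recovery tests therefore compare against realized truth
  where the contract is exact, and against planted truth where it is
  statistical.
* **Sampling is unconditioned**: a simulated CNV can realize zero carriers,
  a class a discovered call set cannot contain (such a variant would never
  be called).  The summary stage reports this class separately, and tests
  that assert the ≥ 1-carrier score bounds first restrict to
  carrier-bearing CNVs, mirroring discovery.
* **Reproducibility**: one global seed drives a named stream per sub-task
  (frequencies, intervals, genotypes, missingness, features), so enlarging
  one component does not perturb the others; identical config + seed is
  bit-identical.
* **Feature tracks**: planned features are constructed to overlap exactly
  their planned CNVs (error if unsatisfiable — e.g. an unplanned CNV
  inside the required span); unplanned features go into CNV-free gaps.
  Planting on isolated CNVs (`isolated_cnv_ids`) guarantees
  satisfiability on dense call sets.

## Numerical choices and degenerate inputs

* Normal-fit p-values require ≥ 3 values with nonzero spread; zero
  variance is an error (the rank method is the suggested fallback), not a
  silent p = 1.
* BH adjustment delegates to `statsmodels` `fdr_bh`; a hand-rolled
  step-up implementation lives in the test suite as the independent
  oracle.
* Interval overlap runs on per-chromosome interval trees
  (`intervaltree`), with the brute-force all-pairs scan as the test
  oracle; intervals touching in exactly one base overlap, adjacent
  intervals do not.
* Ranking tie-breaks are fully specified (genes: score desc, then id;
  QTL: distance asc, then score desc, then id) so outputs are
  deterministic and rerunning a pipeline config is byte-identical.

## Problem sizes

Default simulations run at the emulated study scale (6,811 CNVs × 32
animals), which every stage processes in seconds; the recovery analyses
use 1,000 CNVs × 20 replicate seeds.  These sizes were chosen as the
smallest that make the sampling behaviour of the statistics visible.

## Known limitations

* Deletions only; duplication/insertion CNVs are out of scope.
* Exactly two breeds for the selection scan and breed-specific stages
  (the F formulas generalize, the reporting does not).
* The normal fit for "empirical" p-values is a modelling convenience the
  score distribution only approximately satisfies; with planted outliers
  the fitted σ inflates and power drops — visible in the analysis run,
  where only a fraction of the δ = 0.6 planted CNVs reach FDR 0.01.
* No VCF symbolic-allele importer; the genotype-table layout is the one
  ingestion path.
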