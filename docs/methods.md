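# Methods

`denovokit` implements a germline de novo SNV (DNM) analysis for multi-child
family cohorts: dual-caller candidate merging, a trio filter cascade with
deep-resequencing validation, read-fragment parent-of-origin phasing, Poisson
regression of DNM counts on paternal age, 96-channel SBS spectra, and
mutational-signature extraction and decomposition. Because per-variant data
from such studies are typically not shareable, every stage is driven by a
synthetic cohort generator that embodies the statistical structure the
analysis assumes; the test suite and the acceptance script establish the
pipeline's properties on that generator.

## The generating model

**Pedigrees.** `n_families` (default 13) families; the number of children per
family is `round(Normal(3.7, 1.2))` clipped to `children_range = (2, 6)`.
Paternal age at the first birth is `Normal(23, 4)` years (floored at 16);
interbirth gaps are `Normal(3.4, 1.5)` years (floored at 0.6). These values
reproduce a cohort with mean paternal age ≈ 27.5 y and a ≈ 9 y average span
between first and last child. Maternal ages are not modelled; only paternal
age drives counts.

**Counts.** Each family draws a slope `beta_f ~ Normal(beta_mean, beta_sd)`
with defaults `beta_mean = 1.29` SNVs/year and `beta_sd = 2.4` (the range
estimator applied to thirteen observed family slopes spanning roughly −1.9 to
+6.5, deflated for their estimation noise). The per-child count is Poisson
with mean

    max(alpha + beta_mean·age + (beta_f − beta_mean)·(age − agebar_f), 0.1)

where `agebar_f` is the family's mean paternal age and `alpha = 16.1` is the
baseline at age 0 (chosen so the cohort mean lands near ~52 validated SNVs per
proband at the cohort's mean age). Family slopes pivot at the family's own age
centre rather than at age 0: with a shared intercept, slope heterogeneity of
this magnitude would spread per-child count levels far beyond what multi-child
cohorts show, whereas real families display heterogeneous slopes at similar
count levels (slope–intercept compensation). With `beta_sd = 0` the mean
reduces exactly to `alpha + beta·age`. The 0.1 floor keeps the Poisson mean
positive for strongly negative slopes at young ages.

**Parent of origin** is Bernoulli with `p_paternal = 0.786`.

**Contexts.** Each DNM's 96-channel is drawn from a mixture of generating
signatures; the built-in catalog has a broad clock-like component (`SBSclock`,
T>C- and C>T-leaning) at weight 0.85 and a CpG-deamination component
(`SBSdeam`, 68% of its mass on the four N[C>T]G channels) at weight 0.15. The
CpG component's weight drifts with paternal age (`cpg_age_shift = 0.008` per
year around a pivot of 27.5 y), emulating the age-related rise of CpG C>T
transitions; this is what the age-quartile spectra detect. Channels are then
placed at toy-genome positions whose pyrimidine-strand reference trinucleotide
matches the channel (reverse complement allowed), sampled **without
replacement cohort-wide**, so spectrum reconstruction from genome + positions
is exact and no true site ever trips the recurrence filter.

**Toy genome.** Random sequence at `gc_content = 0.41` with CpG islands
covering `cpg_island_fraction = 0.02` of its 1 Mb default length (200 bp
islands with planted CG dinucleotides). One megabase gives ≈ 30 000 candidate
positions per trinucleotide context — ample for ~2 500 placements.

**Read evidence.** Discovery depth is Poisson(30) per trio member; validation
depth Poisson(300). True-DNM evidence (child alt ~ Binomial(depth, 0.5),
strand split Binomial(alt, 0.5), GQ a saturating function of depth plus
Normal(0, 3) noise, zero parental alt reads) is sampled *conditionally on
clearing the discovery and validation thresholds*; the rejected probability
mass is below 0.5%, so the stated distributions still hold to good
approximation. This defines simulated truth as **recoverable truth**: the
generator models variants a caller would emit and a validation assay would
confirm, and deliberately does not model stochastic dropout of true variants.
Consequently recall against truth is ≈ 1 by construction, and a run with all
artifact rates at zero validates exactly the truth set; the informative
quantity under artifact load is precision.

**Artifacts.** Three classes, with expected per-child rates chosen so that
discovery candidates total ≈ 235 per child (the scale of a DeNovoGear-like
caller on a trio at 30X): `parental_mosaic` (20/child; child evidence like a
true DNM, one parent carrying the allele at a Uniform(0.02, 0.25) fraction),
`seq_noise` (150/child; child allele fraction Beta(2, 18), strand-imbalanced
9:1), and `recurrent` (12.5 occurrences/child; the same site injected into
≥ 2 children with true-like evidence). Mosaics with very low parental
fractions are the designed failure mode: a parent at 2–6% mosaicism often
shows zero alt reads at 30X and passes the 10% AAF validation cut, leaking
through at ≈ 1.5 sites/child and bounding precision near 0.96–0.97.

**Two pseudo-callers.** Caller A emits every record; caller B independently
re-emits each with probability 0.22 plus ~4 private noise records per child,
so |A∩B|/|B| ≈ 0.93 and the merged list reproduces the situation where one
caller's output nearly contains the other's.

**Phasing fragments.** A fraction of DNMs (default 0.104) receives one
informative site 50–400 bp away — father and mother homozygous for different
alleles, child heterozygous — plus 1 + Poisson(2) alt-carrying fragments
linking the DNM alt to the true parent's haplotype allele and a matching set
of reference-carrying fragments. Fragments are abstract (dnm allele, site
allele) observations, not reads; `wrong_parent_rate` (default 0) can inject
conflicting links.

## Filters

Discovery cascade, fixed order, telescoping trace: (1) parental alt fraction
> 10% in either parent; (2) fewer than 2 alt reads on either strand; (3) any
trio depth < 12; (4) any trio GQ < 20; (5) any parental alt read. Stages 1 and
5 overlap deliberately — zero parental support subsumes the fraction rule at
discovery — but both are kept as independently configurable stages because
they exist as distinct checks (the fraction rule is the one that acts at
validation). Inclusive/strict boundaries follow the stated symbols: depth ≥ 12
and GQ ≥ 20 pass; validation requires proband AAF strictly > 0.3, proband
depth strictly > 10, parental AAF ≤ 10%. Because the stage predicates are
variant-local and independent, the survivor set equals a joint one-pass
evaluation regardless of stage order (property-tested against a brute-force
oracle); only the per-stage attribution depends on order.

Recurrence removal is cohort-wide across families: every occurrence of any
(chrom, pos, alt) seen in ≥ 2 children is dropped, with distinct-site and
occurrence counts reported separately (published counts of this step are
mutually inconsistent at the ±5% level, so neither number is asserted).
Candidates without a validation readout go to an explicit "no-bait" bin.

Validation depth is interpreted as **total** depth at the site, with
`val_depth_is_total=False` switching to alt-supporting depth; X-chromosome
candidates are thresholded like autosomes (chromosome is carried in the
output, so a user can re-filter).

The mutation rate is `total / (n_probands × callable_diploid_bp)` with a
binomial CI (normal approximation by default, Clopper–Pearson optional). The
callable-genome denominator is an explicit parameter (default 5×10⁹ diploid
bp), not a derived quantity.

## Paternal-age regression

`PaternalAgeModel(counts, ages, link="identity")` fits a Poisson GLM via
statsmodels. The identity link is the default because the quantity of
interest is additive SNVs per year; the mean is checked to be positive over
the observed age range. When a zero count at an extreme age drives the
unconstrained IRLS solution out of the feasible region, a constrained
maximum-likelihood fallback (SLSQP with μᵢ ≥ ε, Wald intervals from the
observed information) takes over. The log link is available; its slope is
reported as the marginal SNVs/year at the mean age. CIs are Wald by default
with a profile-likelihood option. The cohort fit pools children without
family effects; per-family fits are independent, with singleton families
skipped and flagged. Families are ranked by ascending slope, ties broken by
id.

Two calibration facts shape the tests: Wald CI coverage is evaluated on
cohorts generated with `beta_sd = 0` (coverage is a statement about data from
the fitted model; with slope heterogeneity the pooled model is deliberately
misspecified and nominal coverage is not expected), and per-family slope
recovery is evaluated at the default `beta_sd = 2.4`, pooling 400 simulated
cohorts so the Spearman estimate's own noise (≈ 0.01) is small against the
0.8 decision line; the statistic centres near 0.82–0.83.

## Phasing

A site is informative when the child is heterozygous and exactly one
assignment of its alleles to the parents is consistent with the parental
genotypes. Fragments carrying the DNM alt vote for the parent whose site
allele they carry; a verdict requires ≥ `min_support` (default 1) votes for
one parent and zero for the other; any split vote is a conflict and never
counts as phased. Verdicts are order-invariant. Single-link voting only — no
multi-site haplotype assembly. Summaries report per-family phased and
paternal fractions (families with zero phased calls excluded from the mean,
flagged) separately from the pooled paternal:maternal ratio, since the two
coincide only for balanced families. Autosome-only by default.

## Spectra and signatures

Channel labels use the `X[R>A]Y` text dialect in a fixed substitution-major
order (C>A, C>G, C>T, T>A, T>C, T>G; flanks lexicographic). The classifier
reverse-complements purine-reference sites; N-contexts go to an unclassifiable
bin. A strict-order catalog validator rejects permuted files by default
(`strict_order=False` reindexes complete files with a warning) — published
catalogs sorted flank-major must be loaded permissively. Age-quartile spectra
partition **children**, not SNVs, so sibling spectra are never split; boundary
ages are always reported and a degenerate (single-age) cohort is an error.

Extraction is a stability-selected NMF: per candidate k, each bootstrap
replicate resamples every sample column as a multinomial draw of its total,
factorises with multiplicative-update NMF under the KL objective, and the
pooled replicate signatures are clustered (k-means on unit vectors) into k
consensus signatures. Stability is the mean cosine silhouette (defined as 1
for k = 1, where the solution is the closed-form normalised pooled spectrum);
reconstruction error is the relative Frobenius error after an NNLS exposure
refit on the original matrix. The selected k maximises silhouette among ks
whose error is within a factor 1.2 of the best; ties go to smaller k. This is
a deliberately simplified re-implementation of the standard
extract-then-select practice, validated by recovery properties (two
well-separated generating signatures are recovered at cosine ≥ 0.95 with
k = 2 selected), not by bit-compatibility with any external tool.

Decomposition is greedy forward selection scored by cosine similarity: each
step adds the catalog signature that, after a non-negative least-squares
re-solve over the selected set, most increases the cosine between target and
reconstruction; it stops when the best gain < `add_tol` (default 0.01), then
prunes any signature whose removal costs < `prune_tol` (default 0.01).
Weights are re-solved in Euclidean norm by NNLS even though extraction uses
KL — matching refitting practice and keeping the solve convex — then
L1-normalised into contributions. The greedy trace is monotone
non-decreasing in cosine. Note the tolerance semantics: a mixture component
worth less than `add_tol` of cosine is *by design* not selected, so exact
recovery of arbitrarily small components requires tightening the tolerances.
On identifiable fixtures (pairwise cosine < 0.9) the greedy selection matches
exhaustive subset search.

Strand-resolved 192-channel catalogs collapse to 96 channels either by
dropping the non-designated strand and renormalising (default) or by summing
complementary rows; the mode is recorded in the output's provenance since
the two differ for asymmetric components.

## Problem sizes and determinism

Default analyses run a 13-family cohort (~48 children, ~2 500–3 500 true
DNMs, ~11–14 k discovery candidates) on a 1 Mb toy genome in a few seconds.
The recovery experiments use 500 simulated cohorts for CI coverage, 400 for
slope-rank recovery, 100 multinomial replicates at n = 2479 for decomposition,
and 10 000 random sites for classifier cross-checks. Every stage draws from a
generator seeded as (config seed, stage id), so fixed seeds fix every output
byte-for-byte and stages are insensitive to call order.

## What passing tests do and do not show

The generator emulates summary-level read evidence, not reads: no mapping or
alignment error structure, no indel confusion, no GC- or mappability-dependent
depth, no relatedness errors, and truth is defined as recoverable truth
(stochastic loss of real variants at the evidence level is out of model).
Passing recovery tests therefore demonstrates the correctness and calibration
of the *analysis* — filters implement their definitions, the regression is
calibrated under its model, phasing votes are sound, decomposition recovers
identifiable mixtures at realistic sampling noise — not the end-to-end
sensitivity of any sequencing study. Cohort-specific published values that
depend on undeposited per-variant data (the exact slope, phased fractions,
specific cosine values against proprietary catalogs) are covered by these
property checks rather than reproduced numerically; the arithmetic identities
over printed cohort totals (per-proband and per-family means, caller
intersection, bait fraction, mutation rate at a stated denominator) are
recomputed exactly.

## Known limitations

- Identity-link Wald intervals are slightly conservative at small per-family
  n; the profile option narrows them marginally.
- The constrained-boundary fallback's Wald interval is approximate when the
  MLE sits on the feasibility boundary.
- Greedy decomposition is not guaranteed optimal for catalogs with highly
  collinear signatures (the fixture generator enforces pairwise cosine < 0.9
  precisely to stay in the identifiable regime).
- The extractor's model-selection rule (silhouette subject to an error
  tolerance) is a heuristic; on flat or single-process cohorts it correctly
  prefers k = 1, which is also the honest answer for a two-component mixture
  whose proportions barely vary across samples.
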