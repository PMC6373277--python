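# Methods

This package re-implements, as a tested pipeline over synthetic cohorts, a
trio-based analysis of rare-variant contributions to systemic lupus
erythematosus (SLE) risk: trio-aware genotype refinement, a genotype-based
risk score with per-family parental partitioning, a normalized cross-cohort
gene-panel enrichment test stratified by minor-allele frequency (MAF) and
functional annotation, candidate-variant prioritization, and an ACR
sub-phenotype comparison. This note records the models, the synthetic study
conditions, the numerical conventions, and the design choices that were
genuinely open.

## The synthetic cohort model

### Polygenic liability

Disease liability is additive Gaussian:

    L = sum_j w_j g_j - mu_pop + e,   e ~ N(0, sigma_e^2),

over a panel of `n_common_markers = 120` biallelic markers (dosages
`g_j in {0,1,2}`, population MAFs uniform on (0.05, 0.5]), standing in for
an ImmunoChip-scale marker set at roughly 1:1000 scale. Every marker
carries a weight `w_j ~ N(0, 0.21^2)` — the chip targets known
immune-disease loci, so an all-weakly-causal architecture is the realistic
reading, and it avoids pure noise markers whose inherited sharing would
contaminate a forest-based score with non-causal familial resemblance.
These defaults give a genetic variance of about 2 against environmental
variance 1 (`sigma_e = 1`), i.e. a heritability near 0.66, the accepted
estimate for SLE. A sample is affected when `L > liability_threshold`
(default 4.0 on the centered liability scale, population prevalence about
1% — SLE is rarer still, but a threshold much beyond this makes the
rejection sampler pay for realism the analyses never see).

### One-parent burden concentration

Each family designates one parent (mother/father with equal probability)
as the high-burden parent in `one_parent_fraction` of families (default
1.0). The designated parent's genotypes are drawn at tilted allele
frequencies

    p'_j = clip(p_j + eta * p_j (1 - p_j) w_j / sigma_g, 0.02, 0.98),

where the family's latent burden level `eta ~ N(3.0, 2.0^2)` is clamped at
zero (elevated, never protective). To first order this shifts the parent's
expected genetic liability by `eta` population genetic SDs, so across
families the designated parent has **both** a higher mean and a larger
variance than the population. Both moments matter: an early design that
conditioned the designated parent on an upper liability quantile produced
the mean shift but *shrank* the cross-family variance (a truncated upper
tail is narrow), and the patient's score then correlated more strongly
with the *other* parent — the opposite of the structure these analyses
measure. The tilted-frequency family model is the simplest generative
mechanism we found that reproduces the qualitative findings (higher-parent
score distribution resembling the patients', lower-parent resembling
controls, patient–higher-parent correlation clearly exceeding
patient–lower-parent) robustly across seeds.

Families are rejection-sampled as whole units (both parents redrawn,
child formed by Mendelian transmission, environment redrawn) until the
child is affected, capped at `max_rejection_tries` candidate families with
an explicit error naming `liability_threshold`. The acceptance therefore
reproduces the study's ascertainment: draws from the joint family
distribution conditioned on an affected offspring. A training panel of
1160 affected and 2711 unaffected individuals (the sizes of the original
case–control genotyping study) is sampled from the same population for
the risk-score forest.

### Rare variants

Three layers, all biallelic SNVs on synthetic contigs `chrS*`:

* **Enriched panel injections.** Each patient receives
  `Poisson(panel_rare_rate_background x panel_enrichment_factor)` private
  non-silent coding variants in a 22-gene monogenic-SLE panel (background
  rate 0.15/genome calibrated so that 71 patients at enrichment 2 carry
  about 21 observations, the scale of the emulated study; 5% nonsense).
  Each is heterozygous, transmitted from the **non-designated** parent
  (the "second hit" from the other side of the family), and with
  probability 0.4 marked deleterious, receiving predictor scores in the
  damaging range of all three tools by construction (DANN >= 0.96,
  SIFT < 0.05, PolyPhen2 >= 0.85); non-deleterious injections receive
  sub-threshold scores, and nonsense variants carry no scores (they are
  prioritized on class alone). One optional homozygous nonsense variant in
  *C1QC* (both parents het) mirrors a complement-null patient.
* **Genome-wide private background.** Every patient carries
  `Poisson(25)` private ultra-rare variants (class mix: 45% missense, 5%
  nonsense, 20% silent, 15% promoter, 15% other), each transmitted from a
  random parent so trios stay Mendelian-consistent. These populate the
  `case_background` cells that drive the normalization factor.
* **Shared low-frequency pool.** 1500 sites with population MAF
  log-uniform on (2e-4, 0.05], 1% located in the panel, genotyped
  binomially in all parents (children by transmission) and counted
  binomially in the reference cohort. Because both cohorts draw from the
  same frequencies, per-genome rates in the higher MAF bins agree across
  cohorts by construction, and some truly segregating sites are absent
  from the reference sample — the "not found at all in the reference"
  phenomenon that motivates placing MAF 0 in the ultra-rare bin.

The **reference cohort** (default 1000 diploid genomes) is emitted as
per-variant allele counts (`AN = 2 x n_reference` at fully-called sites):
binomial counts for the pool plus its own private singletons at the same
background rates as patients. Each reference singleton is emitted with
probability `reference_singleton_call_rate` (default 1.0); setting it
below 1 emulates the lower sensitivity of a pedigree-free calling pipeline
for private variants and gives the normalization step a real signal.

Reference MAF annotations are *empirical* (AC/AN for shared sites, 0 for
case-private sites), as they would be in practice.

### Genotype emission and phenotypes

Emitted genotypes equal the truth except for uniform corruption at
`genotype_error_rate` (default 0) on the common-marker matrix; child PL
triples are reconstructed with a phred gap of `pl_gap = 40`. Patients
receive 11 binary ACR criteria at typical adult-SLE cohort frequencies
(renal 38%), resampled until at least four criteria are met; heterozygous
deleterious-variant carriers draw nephritis at `carrier_renal_rate`
(default 0), emulating the nephritis depletion of the candidate subgroup.
Phenotype effects of the panel variants on liability are additive
(`rare_variant_effect = 0.5` per injected variant, applied after
ascertainment so the affected status is never revoked).

### What the generator does not emulate

Read-level noise, indels, CNVs, multi-allelic sites, linkage
disequilibrium between markers, X-linked inheritance, population
structure, and genotype uncertainty in the reference cohort. Passing
recovery tests on these cohorts therefore shows that the *analysis
machinery* measures what the generator encodes — not that real WGS data
would yield the same effect sizes.

## Trio refinement

For each (variant, family), the child posterior is
`P(g | PL, parents) ∝ 10^(-PL_g/10) x T(g | mother, father)`, where `T`
is the Mendelian transmission prior with a per-allele de novo leak
`epsilon = 1e-8` (the order of the human per-site mutation rate). With
both parents missing the prior falls back to Hardy–Weinberg at a supplied
population frequency and the call is annotated accordingly. Quality is
`-10 log10(1 - max posterior)` (capped at Q99), and calls below Q20 are
flagged, strictly: a posterior of exactly 0.99 is Q20 and passes, with a
1e-6 phred tolerance absorbing binary rounding of `log10(0.01)`. The flag
marks rather than removes; the enrichment stage excludes flagged sites by
default, which is this pipeline's resolution of the flag-vs-filter
ambiguity. Phred is taken from the maximum-genotype posterior (not the
GQ-style gap to the second-best); switch at `phred_from_posterior` if the
other convention is wanted.

## Risk score

A `RandomForestClassifier` (500 trees, default feature subsampling, fixed
seed) is trained on the case/control dosage matrix; a sample's score is
the percentage of trees voting "case". Scores are comparable within a run
only — the analyses consume relative structure (partitions, correlations),
never absolute risk, which is also why the in-sample deflation of control
scores (controls are training data) is immaterial here. Markers missing at
scoring time are imputed to the training-mean dosage, with an error below
90% marker overlap (the emulated study had 97.4%). Parent partitioning
takes the higher-scoring parent per family; exact ties break to the
lexicographically smaller sample id and are flagged. Pearson correlations
use the exact t-distribution p value; zero-variance inputs are reported
as undefined rather than raising.

## Panel enrichment

Observations are variant x carrier occurrences; a homozygote counts once
in the default `carrier` mode (matching "N variants identified in M
patients" tallies that count a homozygous patient once) and twice in
`allele` mode. Reference observations use allele counts, which for rare
variants approximate carrier counts. Strata are the cross of
annotation class (non-silent coding = missense+nonsense; promoter) and
half-open reference-MAF bins `(lo, hi]` with default edges
{0, 0.001, 0.01, 0.05, 0.5}; MAF 0 (absent from the reference) falls in
the ultra-rare bin, and MAF > 0.5 is an error, never folded silently.
Panel membership additionally requires the variant to lie in the matching
interval type (coding/promoter) of the panel BED. Sites flagged by
refinement are excluded by default.

Per stratum, the **normalization factor** is the ratio of per-genome
genome-wide (non-panel) rates, case over reference — the
calling-sensitivity correction, largest for private variants. The
**odds ratio** is the normalized per-genome rate ratio

    OR = (case_panel / n_case) / (factor x ref_panel / n_ref),

the scale on which `expected = observed / OR`, so the excess-variant
count is `observed x (1 - 1/OR)`. The p value is a two-sided Fisher exact
test on the genome-count 2x2 table
`(case_panel, n_case - case_panel; round(factor x ref_panel), n_ref - ...)`
— rounding because exact tests need integers; the unrounded OR is always
reported, with a Haldane–Anscombe 0.5 display OR when a zero cell occurs.
An alternative table that uses the background counts as the second margin
was considered and rejected: any uniform calling-sensitivity difference
cancels from that ratio-of-ratios, so the normalization it motivates
either does nothing or (applied to one cell) *introduces* exactly the bias
it should remove; the genome-margin table with a background-estimated
factor both corrects a deflated reference and leaves an unbiased one
untouched. Two-sided p values use minimum-likelihood summation (the sum of
all conditional tables no more probable than the observed one, with a 1e-9
relative tie tolerance), matched in the tests against an exact-integer
enumeration oracle and against the scipy convention. Bonferroni correction
runs across all *tested* strata (untestable strata — empty reference
background — consume no alpha). Signed log p is `-log10 p` with the sign
of `OR - 1`.

## Prioritization and clinical comparison

Candidates are in-panel non-silent coding variants with reference MAF at
most 0.001 surviving the flag policy. The damaging call is
`SIFT < 0.05 or PolyPhen2 >= 0.85 or DANN >= 0.96`, nonsense always
damaging; a missing predictor score counts as non-damaging for that
predictor (logged). The DANN cut sits between the score patterns of
reported damaging candidates (>= 0.96) and the reported
structurally-argued exception (0.362), and all three cuts are
configuration, not facts. Variants failing all predictors are retained
only with a human-supplied evidence note — structural arguments are
judgments the pipeline refuses to auto-assign — and are excluded from the
headline count otherwise.

The ACR comparison is carriers versus **non-carriers** (disjoint groups;
an exact test assumes independent samples — comparing carriers against
"the entire cohort" would count each carrier on both sides), with
carriers-vs-all available for descriptive frequencies. Two-sided Fisher
per criterion, Bonferroni over the criteria tested; zero-variance
criteria report p = 1 and are flagged.

## Study sizes used by the automated checks

Recovery studies use 500-family cohorts with a 2000-genome reference over
ten seeds (enrichment-factor recovery within 30%, correlation-ordering in
at least 9/10 seeds); the exact-test calibration study uses 500 replicate
no-enrichment cohorts at the 71-family scale, testing the ultra-rare
coding stratum of each — a single well-populated stratum per replicate,
because pooling sparse strata makes the discreteness of exact tests
dominate the rejection-rate mixture; the normalization study uses ten
200-family cohorts with `reference_singleton_call_rate = 0.8`. The Fisher
implementation is checked exhaustively against the enumeration oracle on
all 2x2 tables with margins up to 50. These sizes are the package's
standing study conditions; the worked arithmetic examples (excess 10.9
from 21 observed at OR 2.07; 8 carriers among 71 patients as one-in-nine;
10.9 of 71 as one-seventh) are instant.

## Known limitations

* The correlation magnitudes (and the bimodality of patient scores seen
  in the emulated study) are architecture-dependent; the generator makes
  no claim that bimodality must emerge, and no test asserts it.
* Reference observations are allele counts, so `carrier` mode is
  approximate for non-rare reference variants (irrelevant in the rare
  strata the analysis targets).
* The headline candidate count depends directly on the configured
  deleterious fraction of injections; it validates plumbing, not biology.
* With `genotype_error_rate = 0` and strong PLs nothing is ever flagged
  below Q20; the flag path is exercised by unit tests with weak
  likelihoods rather than by the default scenario.
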