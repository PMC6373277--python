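# sle-trio

Trio-based rare-variant analysis of systemic lupus erythematosus (SLE)
risk, as a tested, reusable pipeline exercised end to end on synthetic
cohorts it generates itself.

SLE is a heterogeneous autoimmune disease with heritability around 0.66.
Common risk variants found by GWAS explain part of it; a separate set of
22 genes causes monogenic SLE or SLE-like interferon-pathway disease.
This package implements the analyses that connect the two in
parent-offspring trios with an affected child:

* **Trio genotype refinement** — the child's genotype posterior
  `P(g | PL, parents) ∝ L(g) · T(g | mother, father)` combines the
  caller's phred-scaled likelihoods with the Mendelian transmission prior
  (de novo leak ε = 1e-8); calls below Q20 are flagged (`LOWGP`), and
  parent of origin is assigned for carrier children.
* **Genotype risk score** — a random forest trained on case/control
  common-marker dosages; a sample's score is the percentage of trees
  voting "case". Parents are partitioned per family into higher/lower
  score, and patient–parent Pearson correlations quantify from which
  parent the polygenic burden was inherited.
* **Gene-panel enrichment** — variant×carrier observations in the
  22-gene panel, stratified by functional class (non-silent coding,
  promoter) and reference-MAF bin ((lo, hi], MAF ≤ 0.1% = ultra-rare,
  absent-from-reference counts as 0). The reference expectation is
  rescaled by a normalization factor (case/reference ratio of per-genome
  genome-wide rates in the same stratum — a calling-sensitivity
  correction), and

  `OR = (case_panel/n_case) / (factor · ref_panel/n_ref)`,
  `excess = observed · (1 − 1/OR)`,

  with a two-sided Fisher exact p (minimum-likelihood summation) and
  Bonferroni correction across strata.
* **Prioritization** — ultra-rare in-panel non-silent variants are
  called damaging when SIFT < 0.05, PolyPhen2 ≥ 0.85 or DANN ≥ 0.96
  (nonsense always damaging), yielding a candidate table with zygosity,
  carrier risk score and parent of origin.
* **Clinical comparison** — the 11 binary ACR criteria compared between
  heterozygous candidate carriers and non-carriers (Fisher exact,
  Bonferroni ×11).

The synthetic-cohort generator is first-class, tested code: an additive
liability-threshold disease model over an ImmunoChip-like marker panel,
with the polygenic burden concentrated in one designated parent per
family and ultra-rare deleterious panel variants injected into patients
at twice the background rate, transmitted from the *other* parent (the
"second hit" structure). Ground truth (liability weights, designated
parents, injected variants) is retained for parameter-recovery tests.
See `docs/methods.md` for the model and its assumptions.

## Worked example

The numbered drivers under `analysis/` run the study stage by stage over
a shared artifact directory (the `sle-trio` CLI exposes the same stages):

```bash
python analysis/01_simulate_cohort.py      --seed 1 --out-dir results/run
python analysis/02_refine_genotypes.py     --seed 1 --out-dir results/run
python analysis/03_risk_scores.py          --seed 1 --out-dir results/run
python analysis/04_panel_enrichment.py     --seed 1 --out-dir results/run
python analysis/05_prioritize_candidates.py --seed 1 --out-dir results/run
python analysis/06_clinical_subphenotypes.py --seed 1 --out-dir results/run
```

With seed 1 the drivers print (abridged):

```
5510 trio calls refined; 0 flagged below Q20; Mendelian-consistent fraction 1.0000
mean risk scores (%): patients 49.3 | higher parents 57.7 | lower parents 28.8 | controls 9.3
patient vs higher parent: r=0.452 (p=7.48e-05); patient vs lower parent: r=0.162 (p=1.77e-01)
            class  maf_hi  case_panel  odds_ratio  p_value  significant
non_silent_coding   0.001          24    2.095901 0.000478         True
ultra-rare coding: observed 24, expected 11.5, excess 12.5 (~1 in 6 patients)
           renal      0.000000         0.350877 0.007216     0.079378
```

Reading these numbers: the trios are perfectly Mendelian-consistent (no
genotype errors were simulated); each family has one parent whose score
distribution resembles the patients' (58%) while the other parent
resembles the controls, and the patient's score tracks the higher-scoring
parent (r = 0.45) but not the lower one — the polygenic risk is inherited
mainly from one parent. On top of that background, ultra-rare non-silent
variants in the monogenic-SLE panel are enriched about twofold over the
normalized reference expectation (OR ≈ 2.1, the generator's target was
2.0), an excess of ~12 variants across 71 patients; and none of the
candidate carriers has nephritis versus 35% of non-carriers, a nominal
signal that does not survive correction for 11 criteria — all mirroring
the qualitative findings the pipeline is designed to measure.

`sle-trio all --preset tiny --out-dir /tmp/demo` runs the whole pipeline
on a seconds-scale preset.

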