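# Methods

## Scope and model

`mthetero` analyses somatic single-nucleotide variation in the mitochondrial
genome of paired tumor/normal samples. Its inputs are per-position
alt-allele-fraction tables (one per sample), per-sample mean mitochondrial and
nuclear coverage, a tumor-cellularity estimate per patient, and cohort-level
clinical, nuclear-feature and outcome tables. The stages are:

1. **Somatic mtSNV calling.** The heteroplasmy fraction (HF) of an allele is
   its fraction of reads. A macro-dissected tumor specimen with cellularity
   *c* is a mixture of tumor and normal cells, so the observed tumor HF is
   deconvolved as

       HF_adj = (HF_tumor − (1 − c) · HF_normal) / c,

   clamped into [0, 1]; unknown cellularity is treated as *c* = 1. A variant
   is somatic when ΔHF = |HF_adj − HF_normal| ≥ 0.20 (the comparator is
   configurable; the boundary case matters only for exactly-0.20 values),
   both samples cover the position at ≥100×, and the position is not one of
   the four excluded sites 310, 523, 524, 3107 (alignment-artifact-prone;
   3107 is the historical `N` placeholder), leaving 16,565 callable bases.
   ΔHF is evaluated per alternate allele, so a normal-heteroplasmic allele
   fixing in the tumor is called. The depth filter is applied to both
   samples because an unreliable normal HF corrupts ΔHF symmetrically.
   Positions absent from the normal table entirely are uncallable under the
   paired design and skipped.

2. **Consequence annotation** uses the vertebrate mitochondrial genetic code
   (NCBI translation table 2: AGA/AGG stop, ATA Met, TGA Trp). Light-strand
   genes (ND6) are read on the reverse complement. Genes whose length is not
   a multiple of three end in an incomplete stop codon completed by mRNA
   polyadenylation; those terminal codons are treated as stops, so a
   substitution destroying one is `stop_lost`. At positions inside
   overlapping genes (ATP8/ATP6, ND4L/ND4) the most severe consequence is
   reported. Protein changes are numbered from the initiator methionine.

3. **Copy number.** MCN = 2 × (mito coverage / nuclear coverage); the
   mutation rate per Mbp is n / (MCN × 16,565) × 10⁶ (the raw per-base rate
   is also exposed), and per-locus frequencies are n / (locus kbp × MCN).

4. **Cohort statistics.** The feature matrix has 22 mitochondrial features:
   the 13 protein-coding genes, RNR1, RNR2, the tRNAs as one group, the
   control region, three control subregions (default HV1, OHR, CSB1 — the
   subregions the survival layer acts on; HV2 is computable on demand), plus
   mtSNV count and MCN as numerics. Region membership is positional on the
   circular genome, so a CSB1 hit automatically sets OHR and the control
   region. The zero-burden permutation test redistributes the observed total
   mtSNV count multinomially across patients (uniformly, or with probability
   ∝ MCN) and counts burden-zero patients; p = (1 + #{null ≥ obs})/(1 + B).
   The two-proportion test is the chi-square test with Yates continuity
   correction (matching R's `prop.test`). Burden–covariate associations are
   binomial-family GLMs (statsmodels) with complete separation flagged.
   Nuclear × mitochondrial associations are Spearman correlations on
   pairwise-complete patients; unadjusted p and Benjamini–Hochberg q are
   both reported because families of 22 × k tests inflate false positives.

5. **Survival.** Univariate Cox scans over binary features (plus
   median-dichotomized MCN and burden 0 vs ≥1), with Wald CIs, log-rank p
   and the Kaplan–Meier survival difference at 120 months; features mutated
   in fewer than 2 patients are dropped. Multivariable models adjust for
   age, PSA, T-category and Gleason Score (ordered numeric codes; the
   encoding of these ordinal covariates is a modelling choice surfaced in
   the API). Synergy grouping partitions patients into
   neither/either/both for a (nuclear, mito) feature pair with per-group KM
   tables and pairwise log-rank tests. The three-class signature classifies
   each patient low/intermediate/high from carriage of selected protective
   (HR < 1) and adverse (HR > 1) features, either with a fixed feature split
   or with leave-one-out cross-validation: each held-out patient is
   classified from a univariate log-rank selection (p < 0.05) on the
   remaining n − 1 patients. Mixed carriage is governed by a conflict rule
   (default `high_dominates`, i.e. conservative toward flagging risk).

### Numerical choices

The log-rank test and the single-binary-covariate Cox model are implemented
directly on risk-table arrays (Breslow tie handling, Newton iteration with
step clamping; monotone likelihoods capped at |β| = 20 and flagged
`separated`). The LOOCV signature evaluates a univariate scan in every fold,
which would be prohibitively slow through a general fitting library; the
primitives are cross-checked against lifelines in the test suite and agree
to solver tolerance in the absence of ties. Multivariable Cox fits and
Kaplan–Meier estimates go through lifelines. Permutation draws are batched
multinomials from a seeded `numpy` generator; results are bit-reproducible
given the seed and invariant to patient order.

## Synthetic cohort generator

The generator emulates the structure of a localized prostate-cancer WGS
cohort with known ground truth; its defaults are the study conditions used
throughout the tests:

| parameter | default | rationale |
|---|---|---|
| patients | 384, of which 164 early-onset (age ≤ 50) | cohort composition |
| ages | EOPC uniform 42–50, LOPC uniform 51–76 | medians near 46 / 63.5 y |
| mean mito depth | 13,577× (Poisson per position) | only the mean is known |
| cellularity | uniform 0.70–1.00 | specimens assessed >70% cellularity |
| burden | Poisson, E = exp(−4.03 + 0.063·age) | matches 71.3% / 38.6% zero-burden fractions at ages 47 / 63.5 |
| tumor MCN | −336 + 13.6·age, ×lognormal(0, 0.15), floor 75 | mean ≈ 431, ≈224 more copies at late onset |
| normal MCN | 600 − 5.2·age | ≈86 fewer copies at late onset, declining with age |
| hotspot weights | control region 0.30, coding 0.54, rRNA 0.08, tRNA 0.08 | control-region enrichment (~30% of hits in ~7% of the genome) |
| true somatic HF | uniform 0.05–1.00 | spans sub- and supra-threshold variants |
| allele-fraction noise | Gaussian, sd 0.01 | deep-coverage measurement noise |
| germline heteroplasmies | Poisson, mean 1.5/patient, shared by both samples | population variants the ΔHF rule must ignore |
| BCR hazards | HV1 0.3, OHR 2.5, MYC_gain 2.0, multiplicative on an exponential baseline with 60% 10-year event rate | protective HV1 / adverse OHR structure |
| MYC gain | base rate 0.10, odds ratio 4 given OHR carriage | nuclear–mito co-occurrence |
| censoring | 20% random (strictly before the event) + administrative at 120 months | realistic follow-up |

The observed tumor allele fraction at a somatic site is
`c·HF_true + (1 − c)·HF_normal + ε` — the exact inverse of the caller's
purity adjustment — so noise-free data round-trips exactly (sensitivity =
precision = 1 for variants with true HF ≥ 0.20). Mitochondrial coverage is
`MCN/2 × nuclear coverage`, the inverse of the copy-number estimator.
Tissue-specific normal-only heteroplasmies can be injected
(`normal_only_rate`) to probe false-positive behavior; they are off by
default. Survival times are exponential with multiplicative per-feature
hazards; Cox models are agnostic to the baseline, so recovery tests do not
depend on this choice.

What the generator does **not** emulate: read-level errors and alignment
artifacts (fractions are perturbed with Gaussian noise only), NUMT
contamination, strand bias, haplogroup background, non-exponential hazards,
and informative censoring. Passing tests therefore demonstrate correctness
of the statistical machinery on data satisfying the model's own
assumptions, not robustness to upstream artifacts.

## Test and acceptance problem sizes

Simulation-based checks use sizes chosen to make Monte-Carlo noise small
relative to the tolerance under test: caller oracle equivalence on 200
patients; threshold monotonicity on 100; permutation calibration on 1,000
replicate cohorts of 100 patients (total burden 80, 999 permutations each);
hazard recovery and signature checks on 2,000 patients with no censoring
and an elevated event rate (~68%); null signature coverage on 200 replicates
of 150 patients with 8 inert features.

## Known limitations

* The permutation test's attained type-I error sits slightly below the
  nominal 0.05 (measured 0.024–0.045 across seeds) because the zero-count
  statistic is discrete; the test is conservative, never anti-conservative.
* The LOOCV signature's class-vs-intermediate hazard ratios are **not**
  calibrated under the null: the contrast reuses the outcomes that drove
  per-fold feature selection (folds share n − 1 patients), so conditional on
  any selection the contrast is close to the selection test re-run, and
  naive CIs cover 1 in only ~55% of null contrasts (~72% of replicates).
  There is also a leave-one-out anti-selection effect: for a feature near
  the selection threshold, the fold excluding a patient selects it exactly
  when that patient's own outcome weakened the association, which can push a
  "low-risk" class's hazard ratio above 1. This anti-conservatism of naive
  inference on pre-validated predictors is well documented (Tibshirani &
  Efron 2002, *Pre-validation and inference in microarrays*). The signature
  HRs are reported as descriptive; claims of significance require an outer
  validation cohort or a full outer permutation, which is out of scope.
* The signature's feature-selection criterion (univariate log-rank p < 0.05)
  and the conflict rule for mixed carriage are design choices exposed in the
  API; all three conflict rules are tested.
* The packaged reference FASTA is a synthetic sequence on rCRS coordinates
  (see `data/synthetic_rcrs_like.fasta` and `scripts/make_synthetic_reference.py`);
  real-data analyses must supply a real rCRS FASTA via
  `load_annotation(fasta_file=...)`. The packaged gene map, strands and
  subregion coordinates are the standard rCRS annotation; CSB1–3 default to
  213–235, 299–315, 346–363 and are overridable.
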