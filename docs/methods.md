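# Methods

## Problem and model

Adverse drug reactions split into Type A (common, dose-dependent, arising from
the drug's primary target pharmacology) and Type B (idiosyncratic, largely
unrelated to the drug's main action, often off-target). Variants behind Type B
reactions need not sit in conserved sequence, so predictors built on
cross-species conservation systematically under-call them. The package does
two things: (i) enriches for candidate Type B variants from annotation data
alone, and (ii) quantifies how differently functional-inference tools score
variant classes with different Type B content.

### The cascade

The cascade operates on gene-contextual records — one record per
(rsid, gene), because pharmacogenetic annotations are gene-contextual and one
rsid may be annotated in several genes. Filters, in order: missense
consequence; presence of a Toxicity/ADR effect type; absence of any additional
effect type for the same drug; gene neither PharmaADME nor annotated with an
excluded GO term; and a ClinVar-presence rule. Records removed at step k are
never reconsidered, so retained counts are non-increasing; the result is
invariant under input order.

Open choices and their defaults:

* **Step-3 grouping** (`effect_grouping`): `per_drug` (default) pools effect
  types for a given (rsid, drug) across all gene records before testing for
  non-toxicity effects; `per_drug_gene` consults only the record's own
  annotations. Both readings occur in practice; the default takes the
  pooled-per-drug interpretation.
* **ClinVar rule** (`clinvar_rule`): default keeps variants *with* a ClinVar
  entry (candidate Type B variants should have clinical assertions); the
  opposite reading is available.
* **GO matching** is exact, case-insensitive term-name equality — no substring
  matching, no ontology descent. The exclusion set defaults to
  {"xenobiotic metabolic process", "transporter"}; users whose annotation
  source spells the first term "xenobiotic metabolism process" should supply
  that spelling.
* **Unknown genes** pass step 4 (treated as non-ADME with no GO terms) and are
  logged at warning level, on the principle that missing annotation is not
  evidence of ADME membership.

### Truth-set arithmetic

Against a curated Type A/Type B truth set, the flagged set is summarized by a
2×2 confusion table with Type B positive. `fold_enrichment` is defined as
round½(precision, 2 dp) / round½(prevalence, 2 dp), reported to two
significant figures — the bookkeeping that turns 5/8 and 9/30 into
0.63/0.30 = 2.1. Half-up rounding (not banker's) is used deliberately so
0.625 → 0.63. Degenerate ratios (empty flagged set, zero prevalence) are
reported as missing, never as zero. Standard sensitivity TP/(TP+FN) and
specificity TN/(TN+FP) are exposed alongside; note that precision and
sensitivity differ whenever FP ≠ FN.

## Score conventions and statistics

Normalization maps each tool onto damaging-is-high [0, 1]: SIFT is inverted
(s → 1 − s), CADD and Mutation Assessor are min-max rescaled over a stated
reference row set (by default the union of the positive and negative sets
under comparison, recomputed per comparison, since no absolute score bounds
are defined for these tools), and all other tools are identity-clipped to the
unit interval. Missing values (NA) are first-class and propagate; every
statistic drops them pairwise per tool and reports `n_missing`. The identity
convention is only appropriate for tools that natively emit unit-range scores;
of the eleven, GERP++ (≈ −12…6) and raw FATHMM (lower = damaging) fall outside
this and should be given explicit conventions if benchmarked outside the
default six-tool ROC subset (CADD, PolyPhen2, SIFT, Mutation Assessor,
MutPred, REVEL).

PolyPhen2 scores bin into benign [0, 0.15), possibly damaging [0.15, 0.85)
and probably damaging [0.85, 1]. CADD Phred scores convert to rank fractions
by 10^(−s/10) (10 → top 10%, 20 → top 1%).

* **ROC/AUC**: thresholds are the distinct observed scores; a call is
  damaging when score ≥ threshold, so ties share a point. AUC is the
  trapezoidal integral, which equals the concordance probability
  P(X>Y) + ½P(X=Y) — this identity is enforced by an oracle test against
  brute-force pairwise comparison.
* **MCC**: the single headline MCC per tool is the maximum over the
  threshold sweep (ties broken toward the larger threshold), matching the
  cutoff-sweep behavior of standard ROC tooling; a fixed threshold mode
  (`fixed:<t>`) is available. Zero denominators return 0 by convention.
* **Mann–Whitney U** (category 1 vs each of 2/3/4, two-sided by default):
  exact null distribution for tie-free samples with n1·n2 ≤ 400, otherwise
  the normal approximation with tie-corrected variance and continuity
  correction. Exact enumeration under ties is not attempted — the conditional
  null given observed midranks has no closed small-sample form and full
  permutation is combinatorially infeasible at these sizes; the tie-corrected
  approximation is standard practice.
* **AUC comparison**: the two comparisons' per-tool AUC vectors are compared
  with a paired one-sided t-test (alternative: first > second), Bonferroni
  multiplied by the number of tools and capped at 1. All-zero differences
  report p = 1.

## Synthetic data

The generator emulates the annotation/label/score structure the analysis
assumes — nothing else (no allele frequencies, linkage, or sequence context).
Defaults describe the study-scale composition: category sizes
{1: 119, 2: 183, 3: 130, 4: 129} (561 variants total, with the unreported
category 3/4 split taken as even) plus 2 155 random background variants;
Type B prevalence 0.30 (the truth-set rate); per-class annotation profiles
chosen so expected cascade pass-rates echo the truth-set experiment (Type B
≈ 0.55, Type A ≈ 0.10). Scores come from class-conditional Beta
distributions — Type A (damaging) Beta(8, 2), Type B and random background
Beta(2, 8) — mapped onto each tool's native scale and direction (SIFT
mirrored; CADD on 0–50; Mutation Assessor on −5…6; GERP++ on −12…6), with
independent per-cell missingness (default 5%). Class sizes are count-exact
(rounded expectation) by default so tests are non-flaky; a binomial mode
exists for realism.

`generate_binormal_scores` draws positives from N(δ, 1) and negatives from
N(0, 1) with δ = √2 · Φ⁻¹(AUC), giving a known expected AUC for calibration
tests. `generate_cascade_fixture` plants Type B variants that satisfy every
filter and makes each Type A variant violate one uniformly chosen filter
(or leak with probability `leak_prob`), so expected precision is
planted/(planted + leaked) by construction.

Passing tests on synthetic data show the machinery is correct under the
planted statistical structure; they do not show that real PharmGKB exports
satisfy that structure (e.g. real effect-type annotations are correlated
across drugs, real Type B prevalence varies by evidence category, and real
score distributions are multimodal in ways Beta draws are not).

## Problem sizes and numerical choices

Tests and the acceptance script run at deliberately modest sizes: oracle
equivalence on ≤ 12-per-side samples (500 draws), exact-MWU enumeration up to
n1·n2 ≤ 60, AUC recovery at 2000/2000 over 100 seeds, end-to-end runs at a few
hundred variants. These sizes give tight statistical checks while keeping the
suite fast; the library itself has no size-dependent switches other than the
documented exact/asymptotic MWU rule. All randomness flows through explicit
integer seeds (`numpy.random.default_rng`); generators are pure functions of
(config, seed), and the simulate manifest preserves dict insertion order
because it fixes RNG consumption order.

## Known limitations

* Full-database cascade counts and benchmark values depend on a specific
  PharmGKB/dbNSFP snapshot and are not reproducible from code alone; the
  package reproduces the arithmetic and the machinery, not the snapshot.
* The manual three-criterion Type B literature checklist is represented only
  as truth-label data, never automated.
* No VCF/liftover/transcript resolution: scores are consumed pre-computed per
  rsID.
* Sensitivity/specificity naming in published summaries of this kind of
  experiment is inconsistent; this package always uses the standard
  definitions and additionally reports precision explicitly.
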