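# Methods

## Scope and model

The package implements a marker-discovery-to-assay pipeline for binary
treatment-response prediction from DNA methylation. Its statistical core is:

- **Beta values.** At a CpG, beta = meth/(meth+unmeth) ∈ [0,1]; betas are
  reported only at coverage ≥ `min_coverage` (default 5; a convention of this
  package, since a floor is needed once counts are modelled).
- **Reduced representation.** The library consists of internal XmaI
  fragments: cut positions are site start + 1 (C^CCGGG), fragments are
  inter-cut intervals, and the terminal pieces are excluded because adapter
  ligation needs a cut at both ends. Fragment length is the inter-cut
  distance, so lengths tile the reference exactly. Size selection keeps
  110–200 bp inclusive. CpG enumeration scans each fragment cut-to-cut plus
  the 4-bp filled-in 5′ overhang of the downstream site, which is part of the
  sequenced molecule; this is what guarantees that every library fragment
  carries at least two CpGs (one per CCGGG remnant).
- **Screening.** Per-CpG two-sided Wilcoxon–Mann–Whitney between response
  groups; exact enumeration when both groups have ≤ 8 observations and no
  ties, otherwise the tie-corrected normal approximation. Significance is raw
  p < 0.01 with no multiple-testing correction (a Benjamini–Hochberg option
  exists but is off by default, matching the original screening practice of
  this assay family). TSS restriction keeps CpGs within ±1000 bp of a TSS —
  "belonging to a TSS" needs a distance, and ±1 kb is the conventional
  promoter window.
- **Clustering.** Agglomerative clustering with Manhattan (city-block)
  dissimilarity and the Ward criterion applied to those dissimilarities.
  SciPy's `linkage(method="ward")` on a precomputed condensed matrix performs
  the Lance–Williams update `d(k, i∪j)² = ((n_i+n_k)d(k,i)² + (n_j+n_k)d(k,j)²
  − n_k d(i,j)²)/(n_i+n_j+n_k)` with singleton heights equal to the input
  dissimilarities — identical to R's `hclust(..., method="ward.D2")` given
  the same Manhattan matrix, so results are portable across languages.
  Missing betas are median-imputed per row for clustering and dropped
  pairwise for testing.
- **MSRE-PCR design.** A usable amplicon has ≥ 3 BstHHI (GCGC) occurrences
  fully inside a product of ≤ 200 bp, with the nearest occurrence outside the
  product ≥ 50 bp from each product boundary (region edges count as clear).
  "Three sites" is read as a minimum — extra sites only increase cleavage
  stringency. The scanner returns **every** window satisfying the
  constraints (equal to an exhaustive-substring oracle), sorted by site
  count, then product length; overlapping candidates are flagged, not
  removed. Primer placement and multiplex compatibility are out of scope.
- **Band model and calling.** The digested-lane product survives iff all
  sites in the product are methylated (all-or-none; a single unmethylated
  site is cleaved). A continuous mode returning the protected-template
  fraction (product of per-site methylation fractions, independence assumed)
  is available but not the default. Calling from paired lanes: positive
  control absent → invalid; digestion control surviving → invalid (controls
  are per-reaction, so either failure invalidates the whole sample); mock
  band absent → that locus invalid; otherwise digested band present =
  methylated. Every reading maps to exactly one of {M, U, invalid}.
- **Logistic regression.** Maximum likelihood by Newton–Raphson with
  step-halving, gradient max-norm tolerance 1e-8, maximum 50 iterations.
  Wald SEs from the inverse observed information. Quasi-complete separation
  is detected when any predictor coefficient exceeds 15 in magnitude; the
  fit is returned with a warning rather than an error because the diverging
  MLE still ranks held-out samples correctly, which is all cross-validation
  needs. Odds ratios are exp(β) with 95% CIs exp(β ± 1.96·se); the rounded
  conventional quantile 1.96 is used deliberately, matching field practice.
  Responders (PR) are coded 1 and anchor sensitivity (configurable).
- **Cross-validation.** Stratified 5-fold partitions, 100 repeats; folds are
  stratified because 10 non-responders among 37 samples would otherwise
  often leave a fold with one class. Out-of-fold probabilities are pooled
  *within* a repeat, the repeat's AUC is computed on that pool, and the
  reported AUC is the mean over repeats; the pooled probabilities of all
  repeats feed the ROC and the Youden point. AUC is the tie-corrected
  Mann–Whitney probability (midranks). Youden ties break toward higher
  specificity, then higher threshold. Samples with an invalid call at any
  marker of a combination are dropped for that combination (complete-case).
  Combination search is exhaustive up to `max_combo_size` (default 3) over
  the top `n_combo_candidates` markers by |delta|, ranked by mean AUC with
  ties toward fewer markers.

## Synthetic-data generator

The generator emulates the study conditions, not any particular dataset:

- **Cohort sizes** default to 27 responders / 10 non-responders (the
  validation-cohort structure); the discovery-sized 15/10 cohort is a
  parameter change.
- **Background betas** are two-component mixtures of Beta distributions
  (high component Beta(8,2), mean 0.8; low component Beta(1.5,8.5), mean
  0.15), reproducing the bimodal red/green appearance of island methylation.
  Each sample belongs to a "highly" or "moderately" methylated background
  cluster (high-component weight 0.8 vs 0.3); responders join the high
  cluster with probability 0.8 ("remarkably enriched" has no published
  number; 0.8 gives clear but imperfect enrichment).
- **Markers** sit at TSS CpGs. A sample's marker state is Bernoulli with the
  group's configured methylation frequency; betas are then drawn above or
  below 0.5 accordingly, so "methylated sample" = beta ≥ 0.5 (threshold
  closed on the methylated side). Default panel: 10 markers with PR-minus-SD
  frequency deltas between 0.3 and 0.7, PR more methylated.
- **Reference structure.** Each island (600 bp default) centres a TSS whose
  neighbourhood is deterministic by construction: an XmaI pair 150 bp apart
  brackets the TSS so its CpG lands on a size-selectable fragment, and a
  BstHHI trio spaced 30 bp straddles the TSS with ≥ 50 bp scrubbed flanks so
  an amplicon always exists. Chance motif hits inside those reserved windows
  are mutated away; elsewhere, sites are planted at the requested densities
  (defaults 4 XmaI and 8 BstHHI sites/kb of island).
- **Platform transfer.** Sequencing-derived binary states are flipped
  independently with probability 0.29, calibrated once to the reported
  cross-platform concordance regime (a binary-vs-binary AUC of ≈ 1 − flip ≈
  0.71). Simulated reactions additionally fail a control with probability
  0.03 per control, exercising the invalid-call path.
- **Seed fan-out.** One global seed derives per-stage seeds via
  `SeedSequence((seed, stage_index))`, so each stage is independently
  reproducible and the whole pipeline is bit-reproducible.

What the generator does **not** model: sequencing error profiles, bisulfite
conversion failure, strand merging (only forward-strand CpG positions are
reported), coverage variation between CpGs, batch effects, or correlated
markers beyond the shared cluster structure. Passing tests therefore show
the machinery is correct under the assumed generative structure, not that
the published markers generalise clinically.

## Expected behaviour at study scale

At 27/10 with raw p < 0.01, only the strongest planted markers clear the
screen (3–5 of 10 in typical seeds) while cluster-correlated background
CpGs also enter — an honest picture of small-cohort screening, which is why
the assay panel is defined by the marker specification rather than by the
screen's output. Panel-level CV AUCs land around 0.6–0.8 across seeds with
Youden sensitivities/specificities in the 0.7–0.9 range; these are cohort
realizations, not targets. The cross-platform concordance AUC lands around
0.65–0.77.

## Problem sizes

Defaults were chosen as the package's own working scale: a 17.6 kb reference
(12 islands), ~200 assayed background CpGs, 37 samples, 100×5-fold CV, and
combination search over the top 6 markers up to size 3. The acceptance
script uses n = 200 for the null-marker CV check, 200 replicates of n = 4000
for Wald-coverage, and the defaults above for the end-to-end run.

## Known limitations

- The Mann–Whitney exact path requires no ties; tied small samples fall back
  to the tie-corrected normal approximation.
- Separation makes Wald CIs meaningless (SEs blow up); the fit is flagged
  but the CI columns are still populated from the pseudo-inverse.
- The amplicon scanner is O(region × product length); it is meant for
  kilobase promoter regions, not chromosomes.
- No replication logic for discordant duplicate reactions, and no
  densitometry: band presence is a boolean input.
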