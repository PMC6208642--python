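# Methods

This note documents the models and procedures implemented in
`pneumotype`, the defaults and why they were chosen, the numerical
decisions that affect results, what the synthetic-data generators do and
do not emulate, and the known limitations.

## Abundance model and detection filter

All community analyses operate on **read abundance**: a taxon's fraction
of the microbial (archaea/bacteria/fungi/virus) reads in a sample, taken
as a proxy for transcriptional activity.  Taxa enter the analysis universe
when their read abundance reaches **1% in at least one sample**
(inclusive comparison, `detection_filter`); filtering subsets rows without
renormalising, so surviving proportions keep their original meaning.
Empty samples become all-zero columns with a warning rather than an error.

Alpha diversity offers Shannon entropy (natural log, 0·ln 0 ≡ 0),
Simpson's 1 − Σp², and observed richness.  Rarefaction subsamples reads
without replacement (multivariate hypergeometric) and counts taxa whose
subsampled relative abundance reaches a threshold, averaged over
replicates; at the full depth with threshold 0 it reduces to observed
richness.

Two-assay concordance (`compare_tables`) is Spearman over the **union** of
the two taxon sets with absences entered as 0 — pooled over all
(sample, taxon) observations and per sample.  The common "0 → 10⁻⁶"
substitution is a display convention for log axes only and is never
applied before correlation (Spearman is rank-based, so it would only
matter through ties).

## Taxonomic assignment

`taxassign` mirrors the MEGAN lowest-common-ancestor recipe for
BLAST-tabular hits: hard thresholds first (bitscore ≥ 100, e-value ≤
1e-10, query coverage ≥ 60%), then a per-read **top-percent band** keeping
hits with bitscore ≥ (1 − 10/100) × best; the band is inclusive, so ties
at the best score are always retained.  Multiple HSPs against the same
taxon are deduplicated before the LCA — multiplicity is not evidence.
"Min Score" applies to the bitscore (MEGAN's convention), not the raw
alignment score.

Per-rank tables count a read through its ancestor at that rank; a read
whose LCA sits above the rank is "unassigned" there, and a read with no
retained hit is "unaligned".  For every rank,
assigned + unassigned + unaligned = number of reads — this bookkeeping
identity is property-tested.  Shrinking the top-percent band can only
keep the assignment or make it more specific (fewer hits ⇒ deeper LCA).

## Stratification

### Distance route

Pairwise sample distance is the **square-root Jensen–Shannon
divergence** with natural-log entropies, `d(i,j) = sqrt(H(m) − (H(p_i) +
H(p_j))/2)`, bounded by `sqrt(ln 2) ≈ 0.8326`.  No pseudocounts are
needed: the mixture form is finite with zeros, and sqrt-JSD is a metric
(identity, symmetry and the triangle inequality are property-tested).
This is the standard enterotyping metric.

**PAM** (k-medoids) minimises the summed distance of samples to their
medoids.  When the medoid-subset space is tiny (C(n, k) ≤ 2000) the
optimum is found by direct vectorised enumeration; beyond that the
classic deterministic BUILD + steepest-descent SWAP is used.  The exact
small-instance path exists because BUILD+SWAP is a 1-swap local search
that can stall on instances exactly small enough for exhaustive search to
be cheap; it parallels the exact-small/approximate-large duality used for
the rank tests below.  All ties break to the lowest sample index, so
results are bit-reproducible.

k is chosen over 2…6 by the medoid-based **Calinski–Harabasz** pseudo-F

    CH = [Σ_c n_c d(m_c, m̄)² / (k−1)] / [Σ_i d(i, m_c(i))² / (n−k)]

with m_c the cluster medoid and m̄ the global medoid.  CH is NaN at k = 1
or k = n (undefined) and the maximum float when the within-term vanishes.

### Model route

The **Dirichlet multinomial mixture** is fitted on raw counts (depth
differences are conditioned on; no pseudocounts needed).  The per-sample
log density omits the multinomial coefficient (constant in the
parameters):

    ln P(x_i | α_k) = lnΓ(A_k) − lnΓ(N_i + A_k)
                      + Σ_t [lnΓ(x_it + α_kt) − lnΓ(α_kt)],  A_k = Σ_t α_kt

EM alternates a log-sum-exp E-step with an M-step pairing the closed-form
mixing-weight update and one digamma fixed-point (MM) step per Dirichlet
vector

    α_kt ← α_kt · [Σ_i r_ik (ψ(x_it + α_kt) − ψ(α_kt))]
                / [Σ_i r_ik (ψ(N_i + A_k) − ψ(A_k))]

so the observed log-likelihood is non-decreasing (asserted each iteration
within 1e-8 slack).  α is floored at 1e-10 to preserve positivity.
Initialisation: restart 0 seeds responsibilities from PAM labels on
sqrt-JSD (0.95/0.05 soft one-hot); remaining restarts use random
Dirichlet(1) responsibilities; the best restart by log-likelihood wins.
Convergence: absolute log-likelihood change < 1e-6, max 500 iterations.

The component count is scored by **BIC = −2 loglik + p ln n** with
p = K·T + (K−1) free parameters, minimised over K = 1…6 (ties to the
smaller K).  The reference DMM literature scores models by a Laplace
approximation to the evidence; BIC was chosen for implementability and is
flagged in every report.  With a few dozen samples of several thousand
reads each, BIC's penalty is only a modest multiple of the likelihood
gain an extra component can extract from overdispersed data, so the
model route is trusted jointly with the distance route and the validation
battery, not alone.

### Agreement and core microbes

Labelings from the two routes are matched by Hungarian assignment on the
confusion matrix; reports give the matched mismatch count and the
adjusted Rand index.

A subgroup's **core microbes** are up to 2 taxa that (a) reach mean
within-subgroup read abundance ≥ 0.05 and (b) achieve their
across-subgroup maximum mean in that subgroup; Spearman rho/p over all
samples is reported for every within-core and between-core pair.  This
definition is a documented stand-in chosen for this package: it captures
the intended phenomenon (co-dominant taxa rise together within their
subgroup; dominants of different subgroups trade off under compositional
closure).

## Validation battery

* **Average silhouette width** from the distance matrix; singleton
  clusters score 0.
* **Prediction strength**: 50 random 50/50 splits; PAM on each half; test
  samples classified to the nearest training medoid; each test cluster
  (size ≥ 2) scored by the fraction of its member pairs co-assigned by
  the training classifier; the repeat statistic is the minimum over
  clusters (clusters of size < 2 contribute 1); PS(k) is the mean over
  repeats, with PS(1) ≡ 1.  Decision threshold: PS > 0.8.
* **Simulation test**: a single-component Dirichlet multinomial (which
  preserves overdispersion and the observed library sizes) is fitted to
  all samples as the no-structure null; B = 199 tables are simulated from
  it and scored by CH at the chosen k via the same sqrt-JSD + PAM path;
  the add-one estimator p = (1 + #{CH_sim ≥ CH_obs})/(B + 1) never
  returns 0 and has resolution 1/(B+1) (B < 19 is rejected).  Decision
  threshold: p < 0.05.

A clustering is "supported" iff PS > 0.8 and p < 0.05 (both thresholds
overridable).  Type-I calibration of the simulation test is checked at a
fixed candidate k (k = 3) on null tables: re-selecting k on every null
replicate would measure the selection-biased compound procedure, not the
test itself.  The calibration suite uses 200 null replicates of n = 30
samples × 20 taxa with B = 99 draws each — resolution 0.01 suffices to
check a 0.05-level test, and these sizes keep the suite fast on one CPU.

## Association tests

All tests are implemented from first principles so their exactness
conventions are explicit; scipy/statsmodels act as independent oracles in
the test suite.

* **Fisher exact r×c**: two-sided p = total probability of margin-fixed
  tables no more probable than the observed one; full recursive
  enumeration when the grand total ≤ 300, otherwise seeded Patefield
  Monte-Carlo (100,000 draws, add-one estimator).  A zero margin returns
  p = 1 with a note.  Table probabilities are compared on the log scale
  with a 1e-7 slack to absorb round-off.
* **Event-count chi-square**: expected events proportional to exposure;
  X² with df = groups − 1; expected counts < 1 are flagged.  Exposure for
  the exacerbation screen is the per-subgroup **patient count** (not
  person-years): with events (5, 10, 14) and patients (12, 5, 4) this
  reproduces the published p = 1.3e-5, which person-year exposure does
  not.  The patient counts themselves are derived from the published
  frequencies {0.4, 2, 3.5} and the 21-patient total.
* **Kruskal–Wallis** with average ranks and tie correction, chi-square
  approximation.
* **Mann–Whitney**: exact enumeration of the U distribution when
  n_x + n_y ≤ 12 with no ties (two-sided = doubled smaller tail, capped
  at 1); otherwise normal approximation with continuity and tie
  corrections.
* **Spearman**: rho on average ranks; exact permutation p for n ≤ 9,
  t-approximation beyond.
* **Multiple testing**: Benjamini–Hochberg step-up adjusted p, and a
  single-λ Storey q-value with λ = 0.5 fixed,
  π̂₀ = min(1, #{p > λ}/((1−λ)m)), q = π̂₀ · BH.  The single-λ estimator
  is deterministic and simpler than the smoother; with the small feature
  screens here the difference is immaterial.  Screen thresholds follow
  the published analysis: q < 0.1 for the clinical screen, padj < 0.05
  for pathway-level lists, p < 0.01 & q < 0.01 for the taxon-gene screen.

Clinical features declare their type (categorical / continuous /
event-count) and are dispatched to Fisher / Kruskal–Wallis / chi-square
respectively; missing values are dropped per feature with the used n
reported, never imputed.

## Host-expression screens

Expression is analysed as log2(TPM + 1e-5); the transform is tagged and
refuses to run twice.  The taxon × gene screen is a vectorised Spearman
(rank matrices + t-approximation p) over the detection-filtered taxa; q
is computed over all tested pairs.  Differential expression across
subgroups uses Kruskal–Wallis (Mann–Whitney for two groups) per gene with
BH control — a deliberately assumption-light choice given ~10–20 samples
per subgroup; the report header records it.  Subgroups with < 3 samples
are excluded with a warning.  Gene-set comparisons run the exact
Mann–Whitney per gene, so tiny subgroups carry their honest enumeration
floor (e.g. a 1-vs-5 split cannot give p < 1/3).  The default Th17 set
ships 13 pathway genes (IL6, TGFB1, STAT3, RORC, IL17A among them) and a
36-gene T-helper differentiation panel; both are plain `GeneSet` objects
and user-overridable.

## Synthetic data: what it emulates, and what it does not

`synthio` generates the inputs the analysis assumes:

* **Community**: K planted Dirichlet-multinomial components; sample
  labels from the mixing proportions (or fixed exactly, as the demo does
  with 20/10/4); library sizes lognormal(meanlog 9, sdlog 0.5) — median
  ≈ 8.1k microbial reads, the scale reported for BALF metatranscriptomes.
  Default components (30 taxa) put Dirichlet mass 100 on a disjoint
  co-dominant taxon pair per component over a background of 5 per taxon
  (total concentration ≈ 340, dominant pair ≈ 62% expected abundance).
  These defaults deliberately describe the **well-separated regime** that
  the recovery checks assume — within-component composition spread small
  against between-component separation, so the planted K is identifiable
  from ~40 samples.  Real lung communities are sparser and far more
  overdispersed; passing recovery tests on these defaults demonstrates
  the machinery is correct, not that three subgroups would be found in
  any real cohort.  At realistic overdispersion the BIC-scored DMM route
  in particular will sometimes prefer extra components.
* **Clinical**: smear ~ Bernoulli(p_component) with defaults
  (0.8, 0.0, 0.75) — the middle component is smear-negative, emulating
  the low-biomass subgroup; leukocyte percentages ~ Normal clipped to
  [0, 100] (lymphocytes elevated, macrophages depressed in the small
  third component); exacerbations ~ Poisson with the published
  frequencies (0.4, 2.0, 3.5) events per patient over a 4-year follow-up.
* **Expression**: per-gene lognormal baseline (log2-TPM mean 5, sd 1.5,
  unit per-sample noise), plus planted subgroup shifts (additive log2
  effects) and taxon-linked genes whose log2 expression follows a slope
  times the standardised log relative abundance of one taxon plus
  Gaussian noise — a monotone link, so Spearman recovers it exactly when
  noiseless.

Not simulated: raw sequencing reads, human/rRNA contamination fractions,
taxonomic misassignment, batch effects, or compositional zero-inflation
beyond what the Dirichlet-multinomial itself produces.

Every generator takes a seed and is bitwise-reproducible; the pipeline
derives all stage seeds from the single run seed via named
`SeedSequence` spawns, recorded in the run report.

## Printed fixtures

`paper_fixtures()` carries the small published inputs used by the worked
examples: per-subgroup exacerbation events (5, 10, 14) — 29 in total over
21 patients; derived patient counts (12, 5, 4) (from frequencies
{0.4, 2, 3.5}: 10/2 = 5 and 14/3.5 = 4 are exact, and 12 is the remainder
of 21, with 5/12 ≈ 0.417 rounding to the printed 0.4); bacterial-DNA
medians (77.2, 25.6, 2.7) pg/ml whose high/low and mid/low ratios
truncate to the printed 28-fold and 9-fold; and subgroup sizes
(20, 10, 4).

## Problem sizes used by the test and acceptance suites

Recovery sweeps use the default conditions (n = 40 samples, 30 taxa,
K = 3) over 20 seeds for both k-selection routes; prediction-strength and
simulation checks run on one such dataset at B = 199.  Calibration uses
200 null replicates (n = 30 × 20 taxa, B = 99) for the simulation test
and 20 seeds of 100 × 100 independent taxon/gene pairs for the
correlation screen.  The end-to-end demo is a 34-sample cohort with
planted sizes 20/10/4.  These sizes were chosen so the full suite runs in
a few minutes on one CPU while keeping each statistical check at sensible
power.

## Known limitations

* The BIC score for the DMM component count is anti-conservative for
  heavily overdispersed cohorts (see above); the Laplace-evidence score
  of the reference DMM approach is not implemented.
* The core-microbe definition is this package's own documented stand-in.
* Prediction strength uses unstratified 50/50 splits; with very small
  subgroups (< 4 samples) a split may lose a subgroup entirely, which is
  visible as higher PS variance rather than silently corrected.
* The Fisher r×c enumeration is exponential in principle; the total ≤ 300
  cutoff keeps it practical for screens of a few dozen samples, and the
  Monte-Carlo fallback handles the rest.
* Only the BLASTN-style alignment path is modelled in `taxassign`;
  reconciliation with a second (protein-level) aligner is out of scope.
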