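# Methods

This note documents the statistical models, the defaults and the design
choices behind `haustostage`, and what the synthetic-data validation does
and does not demonstrate.

## Study design and data model

The reference design is a staged bulk-expression experiment over four
sample types of haustorium development — non-infective stem (niS), swelling
(SWE), attaching (ATT) and penetrating (PEN) — with three biological
replicates each (12 libraries). The root input is a transcript × sample
matrix of raw counts plus transcript lengths; the unit of analysis is the
transcript id (e.g. `Cc000593.t1`), with gene-model collapsing (stripping a
trailing `.tN`) used only for "N transcripts from M gene models" reporting.
Missing qPCR cells are allowed and propagate as "not measured"; downstream
correlations exclude them pairwise.

## Normalization

* **CPM** = count / (library size × factor) × 10⁶; the optional factors are
  TMM scaling factors, used in the differential-expression stage.
* **RPKM** = count / (length in kb × library size in millions), on raw
  (not TMM-adjusted) library sizes, since it mirrors mapping-derived
  abundance reporting.
* **log₂** transforms use a configurable offset (default +1), also for the
  max/min columns of the selection reports, so zero-count cells stay finite.
* **Row z-scores** divide by the sample (n−1) standard deviation; constant
  rows map to zeros, not NaN, so clustering stays defined for flat
  transcripts. Whether population or sample sd is used is a genuine free
  choice at n = 12; sample sd was fixed and documented.
* **TMM** follows the published trimmed-mean-of-M-values estimator: for
  each sample against a reference column (the one whose 75th percentile of
  count proportions is closest to the mean of those percentiles), M and A
  are computed over transcripts nonzero in both, the extreme 30% of M and
  5% of A are dropped from each tail, and the factor is 2 to the
  precision-weighted mean of the surviving M values, with the factor vector
  rescaled to geometric mean 1. Trim fractions are the published defaults;
  only the method name, not its constants, is prescribed upstream.

## Differential expression

The NB parameterization throughout is variance = μ + φμ². The chain is:

1. **Expression filter**: keep transcripts with ≥1 count in at least 3
   samples (the smallest group size; configurable) and a summed CPM across
   samples ≥ 3. The "total CPM" clause is read as the sum over samples of
   per-sample CPM — an ambiguous phrase upstream; the reading is a
   documented, configurable default.
2. **Common dispersion** by conditional maximum likelihood on
   library-equalized pseudo-counts: for each group, conditioning on the
   group total removes the mean, leaving
   l(φ) = Σᵢ lnΓ(yᵢ + 1/φ) − n·lnΓ(1/φ) + lnΓ(n/φ) − lnΓ(z + n/φ);
   the single φ̂ maximizes the sum over transcripts and groups, searched on
   [10⁻⁶, 10] in log space. Pseudo-counts come from linear scaling to the
   geometric-mean library — a stand-in for full quantile adjustment that is
   exact for equal libraries and adequate at the moderate depth ratios
   simulated here. Tagwise empirical-Bayes shrinkage is deliberately out of
   scope: a sound common-dispersion exact test carries the discovery logic.
3. **Exact test**: group counts are summed (a sum of n i.i.d. NB(μ, φ)
   replicates is NB(nμ, φ/n)); conditioning on the grand total, the
   two-sided p-value sums the probabilities of all splits no more likely
   than the observed one (ties included within 10⁻¹⁰ relative tolerance,
   so the symmetric split yields p = 1 exactly). With φ = 0 this reduces
   to the exact conditional binomial split test, which the tests verify by
   exhaustive enumeration for all totals ≤ 30.
4. **BH step-up** adjustment across tested transcripts; significance uses
   inclusive thresholds FDR ≤ 0.05 and |log₂FC| ≥ 1.5. log₂FC is computed
   from TMM-scaled CPM group means with a 0.5-count prior to avoid
   infinities.

## Clustering, enrichment, gene significance

* Hierarchical clustering is complete linkage on Euclidean distances of
  z-scored log₂(CPM+1) rows (and of samples on the other axis), cut to
  k = 12 flat clusters by default; k is a parameter since no selection
  criterion for it is prescribed. Cluster ids are relabeled by decreasing
  size, ties by first-member order, for determinism.
* Enrichment is a one-sided hypergeometric test per functional bin,
  computed exactly from log-factorial sums, BH-controlled across tested
  bins (FDR ≤ 0.05). Dot-separated bin codes are hierarchical: a transcript
  in `15.5.30` also counts for `15.5` and `15` (leaf-only testing is
  available), so top-level category summaries aggregate their leaves. The
  universe defaults to the transcripts passing the expression filter — the
  standard over-representation convention, configurable.
* Gene significance GS is the Pearson correlation between a transcript's
  expression and a 0/1 stage-indicator vector, computed on log₂(RPKM+1)
  after discarding transcripts with mean RPKM < 2. GS is invariant to
  positive affine rescaling of the expression row, so the exact measure
  (RPKM, log-RPKM, z-score) only bends the linearity of the response; the
  log scale is the package default and is configurable. p.GS uses the
  exact t-transform with n−2 degrees of freedom, verified against the
  printed (GS, p.GS) pairs of the marker panel at n = 12. Constant rows are
  reported with an explicit `undefined` flag and never pass.

## Candidate selection

Housekeepers must satisfy all of: RPKM > 0 everywhere; mean log₂(RPKM) ≥ 5;
CV ≤ the 10th percentile of the CV distribution **and** MAD ≤ the 10th
percentile of the MAD distribution, both computed on log₂(RPKM+1) rows over
the population already passing the expression criteria (quantiles over the
full transcriptome would be dominated by low-expression noise); and no
significant fold change in any of the six pairwise contrasts.

Markers for stage S must be significantly **up** in S in all three
contrasts against the other stages (the sign requirement is implied by the
selection's purpose and by the uniformly positive z-scores of validated
markers), carry a mean z-score ≥ 1 over S's replicates, and pass the GS
thresholds for S. One stage may be relaxed to 2-of-3 significant contrasts
— mirroring the transitory attaching stage, whose low-abundance markers
rarely clear all three; how many failures the original relaxation allowed
is unstated, so 2-of-3 is the parameterized default. Relaxation is monotone
(the relaxed set contains the strict set), and the housekeeper and marker
sets are disjoint by construction.

## Reference-gene stability

Each method consumes the scale its original publication defines: geNorm
relative quantities 2^(−ΔCq), NormFinder log₂ quantities, BestKeeper raw Cq.

* **geNorm**: M_j is the mean over partners k of sd(log₂ q_j/q_k) across
  samples; the highest-M candidate is excluded stepwise until two remain.
  The final pair shares rank 1 and earlier exclusions rank 3, 4, … —
  matching the published tied rank-1 pairs. V(n/n+1) is the sd across
  samples of log₂ of the ratio of normalization factors (geometric means of
  the n vs n+1 most stable candidates).
* **NormFinder**: after removing each sample's mean over candidates, the
  model estimates per-group intra-group variances v_ig and candidate
  group biases d_ig (centered over groups). The inter-group variance γ² is
  a moment estimate clipped at zero; the bias is shrunk by
  γ²/(γ² + v_ig/n_g), and SV = mean over groups of |shrunk bias| +
  √(v_ig/n_g), so intra-group variability contributes even when no group
  bias is detectable. The original analysis used a packaged implementation;
  this coding follows the published model equations, so small numerical
  differences from specific packages are possible. With fewer than two
  usable groups the method falls back to ungrouped variability with a
  warning.
* **BestKeeper**: the index is the per-sample arithmetic mean Cq over
  candidates (the geometric mean of the underlying quantities); r_j is the
  Pearson correlation of candidate j's Cq with the index. Constant
  candidates have undefined r, are flagged, and rank last. The method's
  full descriptive battery is reduced to the correlation the ranking uses;
  sd is emitted as a descriptive column.
* **Integration**: competition ("min") ranks per method — ascending M,
  ascending SV, descending r; ties share the smaller rank and the next is
  skipped, reproducing the published tie-then-skip rank pattern — and
  GM = (r₁·r₂·r₃)^(1/3) reported to 2 decimals, final ordering ascending.

## RT-qPCR quantification and stage classification

Technical replicates are averaged per gene × sample. Relative quantity is
RQ_s = E^(Cq_min − Cq_s) with amplification efficiency E = 2 by default
(perfect doubling; no efficiency calibration is modeled, E is a parameter).
Reference normalization divides each sample's target RQs by the geometric
mean of its reference RQs. Classification log₂-transforms normalized RQs,
z-scores each gene across samples, and assigns each sample the stage whose
marker set has the highest mean z-score; ties resolve to the earlier
developmental stage and are flagged ambiguous. A complete-linkage Euclidean
dendrogram of the samples is emitted alongside, since the visual
clustering view remains the field's standard presentation; the explicit
decision rule exists to make calls deterministic.

## Synthetic data

The generator emulates the staged design: 4 stages × 3 replicates,
transcripts with uniform lengths (0.5–3 kb) and library sizes (0.8–1.2 M),
NB counts with variance μ + φμ² and a single global seed.

Expression is planted on the RPKM scale and inverted to expected counts via
μ = RPKM × length_kb × library_millions, so constant-RPKM housekeepers are
constant after normalization rather than in raw counts. Three roles exist:

* **housekeepers** (default 20): stage-constant levels drawn high
  (log₂ RPKM 5.5–8 nominal), with *no* extra biological variability and
  near-Poisson gene-level dispersion (`hk_dispersion` = 0.002). Stability
  is the defining property of a reference gene: a gene whose counts carry
  the transcriptome-average overdispersion cannot exhibit the CV ≈ 0.01 /
  MAD ≤ 0.07 replicate scatter observed for validated references, so
  planting them at the common dispersion would make the low-variance
  criterion physically unsatisfiable.
* **markers** (default 10 per stage): levels boosted by
  2^`marker_effect_log2fc` (default 3 log₂) in exactly one stage.
* **noise** (the rest): stage-constant levels spread over a broad
  log-normal range (sd 1.5 log₂).

All non-housekeepers receive per-sample log-normal biological variability
(`bio_sd_log2` = 0.5), the replicate-to-replicate scatter of real tissue
pools; without it every stage-constant transcript would be as stable as a
housekeeper and a 10%-quantile variance criterion could not single out the
planted ones.

Because a down-scaled transcriptome (10²–10⁴ transcripts) concentrates the
sequencing depth, realized RPKM exceeds the nominal planted levels by a
constant per-dataset offset; all ratio-, variance- and correlation-based
criteria are unaffected, but absolute-abundance cuts (mean log₂ RPKM ≥ 5,
mean RPKM ≥ 2) are effectively always passed in simulation and are
therefore not exercised by the recovery tests.

The Cq model inverts quantification: Cq = intercept − log₂(expr)/log₂(E) +
N(0, σ), two technical replicates per cell, σ = 0.2 cycles by default.

**What passing the recovery tests shows — and does not.** With the default
conditions (3 log₂ effect, φ = 0.05, 3 replicates per stage) the pipeline
recovers ≥ 90% of planted markers per stage with zero cross-stage
misassignment, ≥ 80% of planted housekeepers, and ≥ 90% correct end-to-end
qPCR stage calls. The generator does not model batch effects, GC or length
bias, correlated co-regulation, isoform switching, partially graded (rather
than binary) stage specificity, or amplification-efficiency miscalibration;
recovery under the planted model validates the selection logic, not
performance on any particular real dataset.

## Problem sizes and numerical choices

Tests and validation runs use 300–600 transcripts with 10–20 planted
housekeepers and 5–10 markers per stage — large enough for the quantile
criteria and FDR control to be meaningful, small enough that the full suite
runs in seconds. Exact-test tie comparison uses a 10⁻¹⁰ relative log-scale
tolerance; the dispersion search runs in log space with xatol 10⁻⁸;
distance ties in clustering break by lower item index (via the stable
merge order of the linkage), making partitions deterministic across
platforms. Degenerate inputs fail loudly: all-zero sample columns,
non-integer counts, Cq values outside (0, 45], single-replicate dispersion
groups and empty filters all raise validation errors naming the offender.

## Known limitations

* The exact-test path approximates full quantile adjustment by linear
  library equalization and uses a single common dispersion; results will
  differ in detail from tagwise empirical-Bayes implementations.
* NormFinder follows the published model equations, not any specific
  package's numerical conventions.
* The hierarchical-clustering k (default 12) is a display-level choice, not
  an inferred quantity.
* Headline dataset-level counts from the original staged experiment (e.g.
  thousands of differential transcripts) depend on the archived sequencing
  data and are outside what synthetic validation can or should reproduce.
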