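# Methods

`leafprint` implements a complete flow-infusion electrospray ionisation mass
spectrometry (FIE-MS) fingerprinting analysis: spectral binning, accurate-mass
annotation with consensus chemical-taxonomy classification, random-forest
(RF) permutation statistics, diurnal trend clustering, and structural /
functional enrichment.  This note records the models, the tunable parameters
and their defaults, the numerical choices, and what the synthetic study
generator does and does not emulate.

## Spectral binning

FIE-MS acquires a few minutes of centroided scans per sample with no
chromatographic separation; a sample's fingerprint is the per-bin average of
centroid intensities over the infusion peak.

* **Bins** are half-open intervals `[k*w, (k+1)*w)` of width `w = 0.01` m/z
  over the acquisition window m/z 55–1200, one feature per bin per ionisation
  mode, named `<p|n><lower edge at 2 dp>` (e.g. `n341.11`).  Centroids that
  fall exactly on a boundary belong to the upper bin; a 1e-6 relative nudge
  in the index computation keeps float-represented boundary values there.
* **Infusion window**: the longest contiguous run of scans whose total ion
  count is at least `tic_fraction = 0.5` of the maximum scan TIC (ties go to
  the earliest run).  Bin values are averaged over the window's scans.
* **Accurate m/z**: each bin stores the intensity-weighted mean m/z of its
  centroids (combined across samples by intensity weight).  This is the
  observed mass that annotation uses — the geometric bin centre of a
  0.01-m/z bin can sit tens of ppm from any real ion mass at low m/z, which
  would make low-ppm annotation meaningless, whereas the weighted centroid
  mean preserves the instrument's mass accuracy through the binning step.
* **Filters**, applied in a fixed stage order (raw → occupancy_filtered →
  qc_filtered → normalised → log2) that the containers enforce:
  * *Occupancy*: keep a bin iff, in at least one class, the fraction of
    biological samples with non-zero intensity is ≥ `2/3`.  Detection is a
    class property, so the best class decides.
  * *QC RSD*: keep a bin iff its relative standard deviation (n−1 s.d. /
    mean) over pooled-QC injections is ≤ `0.5`; bins with zero QC mean are
    unassessable and dropped.  Both thresholds are conventional
    fingerprinting defaults and are config-exposed.
  * *Normalisation*: every sample row is scaled to the median
    pre-normalisation row sum (deterministic and scale-free; no reference
    sample needed).
  * *log2*: zeros are imputed with half the global minimum non-zero value
    (monotone, order-preserving), then values are log2-transformed.
* **mzML I/O** is deliberately minimal: the reader handles the
  fingerprinting-relevant subset (polarity and spectrum-type cvParams,
  32/64-bit plain or zlib-compressed arrays) with stdlib XML parsing, and the
  writer emits exactly that subset.  Profile-mode spectra are rejected with
  instructions to centroid.

## Accurate-mass annotation

Features carry no MS/MS or retention evidence, so annotation is by accurate
mass under electrospray adduct rules: an adduct taking `n` copies of neutral
mass `M` with mass shift `s` and charge `z` is observed at `(n·M + s)/z`.
Shifts are computed from a compiled-in monoisotopic atomic-mass table
(CODATA/AME values) and include the electron mass of the charge carrier.
The default rule set is positive `[M+H]+ [M+Na]+ [M+K]+ [M+NH4]+ [2M+H]+`
and negative `[M−H]− [M+Cl]− [M+HCOO]− [2M−H]−`, each with an applicability
predicate over the neutral formula (deprotonation requires ≥ 1 H); rules are
config-extensible.

Candidates are every (formula, adduct) pair whose theoretical m/z lies
within `tolerance_ppm = 3` of the bin's accurate m/z (the instrument-class
mass accuracy; the operative cut-off is configurable).  Primary-source
compounds are searched first; a fallback source is consulted only when the
primary search yields nothing — mirroring a curated-first, broad-second
lookup strategy.

**Consensus classification**: because an accurate mass rarely identifies one
compound, each feature receives the deepest taxonomy lineage that a
threshold fraction (default `0.66`) of its matched compounds share.  The
walk starts at the most general level; at each level the modal term's
frequency is computed over the compounds still consistent with the accepted
prefix (compounds whose lineage ends above the level stay in the
denominator but cannot vote); the walk stops at the first failure, and an
exact modal tie stops conservatively at the previous level.  Consensus is
computed over distinct matched compounds, not (compound, adduct) products.

## Random-forest statistics

Forests are bagged CART trees (Gini for classification with
`mtry = sqrt(p)`, variance reduction for regression with `mtry = p/3`,
fully grown, 1000 trees by default).  The trees themselves are built by
scikit-learn's Cython tree builder, driven directly so that each fit retains
its bootstrap membership and costs ~0.3 ms — permutation testing refits a
fresh forest per permutation, so per-fit overhead dominates the analysis
runtime.  A unit test pins the engine tree-for-tree against
`DecisionTreeClassifier`/`DecisionTreeRegressor` under identical parameters
and random state.

* **Margin**: per sample, the fraction of out-of-bag (OOB) trees voting its
  true class minus the largest OOB vote fraction for any other class; the
  statistic is the mean over samples.  OOB hard votes avoid resubstitution
  optimism.  Samples with no OOB trees (vanishingly rare beyond ~25 trees)
  are excluded.
* **Permutation test**: labels (or the regression response) are permuted
  `n_perm` times (default 3000, config-reducible), the statistic recomputed
  with a freshly seeded forest each time, and
  `p = (1 + #{null ≥ observed}) / (1 + n_perm)` — the add-one rule keeps
  p > 0.  The p-value's validity rests only on exchangeability, not on
  forest size, so calibration checks may use small forests.
* **Proximity**: fraction of trees in which two samples share a terminal
  node, counted over trees where both are OOB; `1 − proximity` is the
  dissimilarity (it need not satisfy the triangle inequality, so no metric
  property is assumed downstream).
* **Ordination**: classical (Torgerson) scaling — double-centre `−D²/2`,
  embed on the top-2 eigenpairs; deterministic up to axis sign; negative
  eigenvalues (non-Euclidean input) are truncated with a logged warning.
  Per-class 95% confidence ellipses use the sample mean and covariance with
  the chi-square(2 df) quantile boundary.
* **Pairwise class dendrogram**: a binary RF margin per class pair, treated
  as a dissimilarity (larger margin = more separable = farther) under
  average-linkage clustering; label order breaks ties; margins can be
  slightly negative, so the matrix is shifted by its minimum before
  clustering.
* **Regression**: OOB `R² = 1 − MSE_oob / var(t)`.  Feature importance is
  %IncMSE — the relative rise of forest OOB MSE when a feature's OOB values
  are permuted within each tree; trees that never split on a feature
  contribute nothing for it.  Per-feature significance comes from a single
  response-permutation null (each permutation refit also yields a full
  importance vector), and the explanatory set is `importance p < 0.05`
  without multiplicity adjustment — raw-p selection is the convention for
  this screening step.  The same null serves the model-level R² p-value.

## Trend clustering

Each explanatory feature's diurnal profile is the median log2 value per
timepoint minus the baseline (09:00) median — a difference of log2 medians,
i.e. the log2 of the median abundance ratio.  The baseline entry is zero by
construction and the profiles are invariant to sample-wise additive shifts.
Profiles are grouped by Euclidean k-means (`k = 5` by default, 10 seeded
restarts, best inertia kept); cluster ids are renumbered by decreasing size
for stable output.  An elbow/silhouette report over a k range is available
so users can justify k.  Per-feature box-plot summaries use textbook
quartiles (linear interpolation), whiskers clipped to the most extreme
points within 1.5 IQR of the quartiles, and everything beyond as outliers.

## Enrichment

* **Structural**: per cluster and taxonomy term, a one-sided Fisher exact
  test (hypergeometric upper tail) on {in cluster vs not} × {annotated vs
  not}, against the background of all classified explanatory features, with
  Benjamini–Hochberg adjustment within each cluster (switchable to
  Bonferroni).
* **Functional**: compounds matched to the cluster's features seed a
  personalized PageRank (restart mass uniform on the seeds, damping `0.85`)
  over an undirected compound–reaction–pathway graph.  Significance is an
  empirical *p-score*: the add-one tail probability that an equally sized
  random compound seed set scores the node at least as high, over `n_null`
  draws (default 1000).  Smaller p-scores mean better connectivity to the
  observed compounds; the add-one rule means a p-score can never be exactly
  zero, so headline values of "0.0000" in this kind of table are rounded.
  The three-layer graph is a deliberate simplification of richer metabolic
  hierarchies; the node-type list is extensible.

## Synthetic study generator

The generator emulates a two-garden, four-timepoint tea-leaf fingerprinting
design with fully known ground truth.  The latent model is additive on the
log2 scale (multiplicative log-normal on the raw scale — the standard noise
model for MS intensities):

    log2 x[s, b] = baseline[b] + class_shift[b]·1{group(s) = target}
                   + archetype[b][time(s)] + N(0, noise_sd)

* Baselines are drawn log-uniform (log2 in [10, 20]).  Defaults: 2 classes ×
  24 samples, 500 bins, 10 discriminating bins shifted ±`effect_size = 0.9`
  log2 units (3 × the default `noise_sd = 0.3`) in one class with
  alternating sign, five trend archetypes of 20 bins each, 5 pooled-QC
  injections with multiplicative noise targeting `qc_rsd = 0.10`.
* **Time encoding**: clock labels 09:00/12:00/18:00/00:00 map to hours
  0/3/9/15 since first sampling; midnight is the night after the 18:00
  collection (a single-day design).
* **Dropout**: only values below the 25th intensity percentile can be
  recorded as zero (probability `zero_rate = 0.1`), emulating
  detection-limit dropout rather than missingness at random; QC rows, being
  pooled averages, are not zero-inflated.
* **Archetype identifiability**: the rise-then-fall archetype is
  `(0, +1, +2, −1)` — build-up through daylight, peak at 18:00, overnight
  depletion below the morning baseline, as photosynthesis-driven sugars
  behave.  A shape symmetric about the peak (e.g. `(0, +1, +2, +1)`) would
  give the 12:00 and 00:00 samples identical feature offsets, making the
  sampling hour unidentifiable between them and capping the hour-regression
  OOB R² near 0.46 regardless of forest quality; all default archetypes
  keep every timepoint pair ≥ 1 log2 unit apart (≥ 3 noise s.d.).
* **Scan emulation** (`matrix_to_scans`) spreads each bin's intensity over
  `n_scans` scans along a triangular infusion profile, scaled so that the
  mean over the scans the default 50%-of-max-TIC window selects equals the
  matrix value — making binning ∘ emulation the identity at zero centroid
  jitter (to 1e-9 relative).  Scan TICs therefore follow the triangular
  shape up to that known scale factor rather than summing to the row total;
  the two normalisations are mutually exclusive and the round-trip identity
  is the property the pipeline's tests rely on.  Centroids are jittered
  uniformly within ±`centroid_jitter_ppm` of the bin's true m/z; jitter
  exceeding half a bin width is refused because it would break round-trip
  bin identity.  Compound-backed bins are planted at the exact theoretical
  m/z of one adduct per reference compound, skipping ions within 0.1 bin
  widths of a bin edge so that small jitter cannot cross bins.
* **Toy reference**: distinct CHNO formulas with masses from the
  atomic-mass table, a taxonomy tree rooted at "Organic compounds" with
  field-typical superclasses, and compound→reaction→pathway membership
  edges; ~20% of compounds are tagged as fallback-source to exercise the
  two-stage search.  A compound's primary pathway fixes its superclass,
  since pathway members share chemistry (flavonoid pathways hold
  flavonoids).
* **Pathway-coherent trends**: when a reference is supplied, trend
  archetypes are planted preferentially on compound-backed bins grouped by
  their primary pathway (pathway → archetype round-robin), emulating the
  co-regulation that makes pathway members rise and fall together over the
  day.  This coherence is what gives cluster-level structural and
  functional enrichment real signal to detect; without a reference, planted
  bins are chosen uniformly at random and enrichment outputs are flat by
  construction.

**What the generator does not emulate** — chromatography, isotope envelopes,
in-source fragmentation, ion suppression, batch/run-order drift, and the
actual chemistry of tea leaves.  Passing tests therefore demonstrate that
the statistical machinery is correct and well-calibrated under the stated
noise model, not that any particular real-world dataset would yield the same
effect sizes.

## Problem sizes and runtime choices

The shipped configurations are desk-scale by design: the demo pipeline runs
the full 48-sample × 500-bin study with forests of 200 trees and 200
permutations / null draws (minutes on one CPU); calibration checks use 200
replicate null datasets of 40 samples × 300 features with 200-permutation
tests on 25-tree forests (permutation validity does not depend on forest
size); power and recovery checks use 50 replicates at the default planted
effects.  Full-scale settings (1000 trees, 3000 permutations) remain the
library defaults for real analyses.

## Known limitations

* Annotation is Level-2 putative by construction (accurate mass only); a
  `confirmed_level` column is the hook for users who confirm compounds
  against standards.
* The QC filter assumes pooled-QC injections exist; without ≥ 2 QC rows the
  stage refuses rather than silently passing everything.
* `1 − proximity` distances are not metric; ordination of them can produce
  negative eigenvalues, which are truncated (and logged), so embedded
  distances underestimate badly non-Euclidean structure.
* The empirical p-score resolution is bounded by `1/(n_null + 1)`; ranking
  among very well-connected pathways saturates at the smallest achievable
  p-score.
* Between-batch drift correction is out of scope; run order is recorded in
  the sample table for users who need to model it.
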