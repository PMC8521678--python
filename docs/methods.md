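# Methods

This note documents the models and procedures implemented in `lrtme`,
the defaults and why they were chosen, what the synthetic generators do
and do not emulate, and the numerical conventions that matter for
reproducing results.

## Gating and phenotyping

A cell is **positive** for a marker iff its intensity is *strictly
greater* than the marker's cutoff. The strict inequality makes boundary
behavior deterministic; a cell sitting exactly at the cutoff is
negative. Gating is idempotent and monotone (raising a cutoff never
increases the positive count).

When no cutoffs are supplied, the default is a per-marker **exact Otsu
split of log intensities**: the between-class variance
w₀w₁(μ₀−μ₁)² is evaluated at every cut between consecutive sorted
observations and the midpoint of the optimal gap is returned. The exact
variant (rather than a histogram-binned one) matters here: with a
bimodal log-normal mixture whose populations are separated by a wide
empty gap, a binned implementation can return a cut at the gap's edge or
even inside the bulk mode, misclassifying boundary cells; evaluating the
empirical objective directly locates the gap and centering the cut in it
gives a symmetric noise margin. This is appropriate for intensity
distributions that are approximate two-component log-normal mixtures —
which is exactly what the synthetic generator produces — and is a
heuristic, not a guarantee, on real inForm-style exports, where
thresholds should be reviewed or supplied explicitly.

**Phenotypes** are named sign patterns over markers (e.g. the TFH-like
population CD4⁺PD-1⁺CXCL13⁺CXCR5⁻). Assignment is priority-ordered:
definitions are evaluated in list order and the first full match wins,
unmatched cells are labeled `other`. One label per cell keeps the
spatial denominators unambiguous; the default panel's definitions are
mutually exclusive anyway, so priority only resolves the HRS-first
convention (a CD30⁺CD4⁺ double-positive would be called HRS).

**Coexpression patterns** count, for each cell, the *exact* subset of
panel markers it is positive for (the quantity an UpSet plot displays).
Counts are exclusive and always sum to the number of cells. For
expression input, positivity defaults to any nonzero log-normalized
value — the conventional detection rule in sparse single-cell data; the
cutoff is configurable.

## Spatial statistics

All statistics use Euclidean distances between cell centroids with an
**inclusive boundary** (d ≤ r); boundary cases are measure-zero for
continuous coordinates, and the inclusive reading of "within r" is the
conventional one. Defaults: neighborhood radius **75 µm**, touching
distance **10 µm**, rosette minimum **5** ring cells.

- *Neighborhood proportion*: the region around a reference population is
  the union of disks of radius r centered on its cells; the denominator
  is every non-reference cell in the region (cells in overlapping disks
  counted once), the numerator the target cells there. A sample with no
  reference cells or an empty region yields an *undefined* statistic
  (flagged, never silently 0) — an empty region is absence of evidence,
  not evidence of absence.
- *Nearest-neighbor distance*: per reference cell, distance to the
  closest target cell; summarized per sample by the arithmetic mean
  (median available as an option).
- *Touching pairs*: cross-phenotype pairs with center distance at most
  10 µm, roughly one lymphocyte diameter. This approximates membrane
  contact on centroid-only data; membrane polygons are not available in
  the table format, so "touching" is necessarily a proxy and the
  threshold is exposed.
- *Rosettes*: an HRS cell is rosette-positive when at least
  `rosette_min_cells` ring-phenotype cells lie within the neighborhood
  radius. No quantitative rosette definition exists in the
  histopathology literature beyond "a ring of surrounding cells", so the
  minimum count is a package choice, prominently configurable; a case is
  rosette-positive when any rosette is present (minimum fraction
  configurable).

Neighbor queries run on a k-d tree but are exact: the test suite checks
equality with O(n²) brute-force scans, and all statistics are invariant
under rigid motions of the coordinates.

Per-sample statistics are compared between groups with Welch's t-test
(two groups) or one-way ANOVA (more), excluding undefined samples with
an explicit count.

## Expression analyses

The expression container is an `AnnData` holding log₂-normalized values
(counts scaled per cell to a fixed library size, default 1000, then
log₂(x+1)). With this convention a log₂ fold change is a *difference of
mean log values*, matching the volcano-plot axis. Cluster labels are
inputs — clustering and batch correction are out of scope.

- *Differential expression*: per-gene two-sided Wilcoxon rank-sum on the
  log values (the dominant convention for within-cluster single-cell
  comparisons; Welch's t is available), BH-corrected across all tested
  genes. For tiny groups (≤ ~3000 possible relabelings) the rank-sum p
  is computed by exact enumeration, which handles ties correctly where
  the normal approximation does not. Significance = q < 0.05 and
  |log₂FC| ≥ 1 (both configurable).
- *Diffusion map*: Gaussian kernel exp(−d²/2ε²) on Euclidean distances
  in gene space; density normalization K/(qᵢqⱼ); row-stochastic
  transition matrix; embedding = leading nontrivial right eigenvectors
  scaled by their eigenvalues (the trivial constant eigenvector is
  discarded). The eigenproblem is solved through the symmetric
  conjugate D^{-1/2}KD^{-1/2} for numerical stability and verified
  against a direct eigendecomposition of the explicit operator. The
  bandwidth ε defaults to the median pairwise distance of a seeded
  ≤500-cell subsample — the standard median heuristic. Each component's
  sign is fixed by requiring positive correlation with the first
  alphabetical gene with |r| > 0.1, making "dimension 2" reproducible
  across runs and platforms. Input consisting solely of duplicated
  cells is rejected as degenerate.
- *Gene–dimension correlation*: Pearson r (Spearman optional) between
  each gene and a component score, sorted descending with lexicographic
  tie-breaks; zero-variance genes are reported as undefined, not 0.
- *Interaction scores*: for each (ligand, receptor) pair, score =
  mean ligand expression over sender cells × mean receptor expression
  over receiver cells, computed per condition; `delta` = score(LR) −
  score(other) so positive values mark LR-enrichment. The score is a
  mean-expression product (the simplest of the published
  receptor–ligand scoring schemes); an optional permutation p shuffles
  condition labels over the involved cells (seeded, default 1000
  permutations, +1 correction). Pairs naming absent genes are skipped
  with a warning rather than silently dropped. The built-in 20-pair
  panel contains CXCL13→CXCR5 plus 19 common immune signaling pairs as
  background.

## Cohort and survival statistics

- Percentages are rounded **half-up** to integers using exact rational
  arithmetic (5/26 → 19%), matching how clinical case fractions are
  printed.
- 2×2 crosstabs report the sample odds ratio ad/bc with a 0.5
  continuity correction when any cell is zero (closed-form and
  oracle-checkable, unlike the conditional MLE) and a two-sided Fisher
  exact p.
- Status–marker correlations are point-biserial (Pearson on 0/1 status
  vs a continuous per-case level), BH-corrected across the computed
  matrix; zero-variance inputs are undefined and flagged.
- The **Kaplan–Meier** estimator and the **two-group log-rank test**
  are implemented directly: the product-limit recursion over distinct
  event times, and the O−E statistic with hypergeometric variance at
  each event time, χ² on 1 df. Implementing them in-package exposes the
  internals the analyses need (per-group observed/expected events,
  risk-set sizes, landmark lookups on the right-continuous step
  function) and lets an independent library (lifelines) serve as a pure
  cross-check in the tests. O−E sums to zero across groups on every
  dataset by construction.
- Biomarker stratification defaults to a **median split** with ties to
  "low" (strictly-greater rule) — the conventional choice when no
  validated cutoff exists for a continuous biomarker — and records the
  cutoff and rule in its output so the decision is visible downstream.

## Synthetic data: what it emulates, and what it does not

The generators produce data with the statistical structure the analyses
assume, plus ground-truth labels, so every estimator can be validated
against planted truth. Defaults (all in `lrtme.synthetic`):

- **Spatial maps**: 1000×1000 µm fields; 10 HRS cells per sample placed
  by dart-throwing with ≥160 µm spacing and a boundary margin of
  ring radius + 3·jitter; half of HRS cells receive a planted ring of 6
  CD4⁺PD-1⁺CXCL13⁺CXCR5⁻ cells at radius 20 ± 2 µm (radial noise
  truncated at ±3σ); 800 background cells/mm² drawn from
  subtype-specific phenotype mixtures (LR fields richer in TFH-like and
  CXCR5⁺ B cells). The 160 µm spacing exceeds 75 + 20 + 6 µm so that no
  planted ring can fall inside another HRS cell's detection disk —
  without this the planted ground truth would be ambiguous at the
  default radius. The background density of the ring phenotype is kept
  low (~24 cells/mm² in LR, i.e. ~0.4 expected per 75 µm disk) so
  chance rosettes are vanishingly rare. Intensities follow a
  two-component log-normal per marker (positive μ=3.0, negative μ=0.0,
  σ=0.25 on the log scale): the simplest model that makes threshold
  gating well-posed, with a gap wide enough that default Otsu gating is
  near-exact even for markers whose positive population is ~1% of cells.
- **Expression**: per-cell cluster drawn multinomially from
  subtype-specific composition vectors (LR: Treg 0.02, naïve B 0.28;
  other CHL: Treg 0.15, naïve B 0.10 — the planted depletion/enrichment);
  counts negative-binomial (size 2.0, Poisson in the ∞ limit) around
  2^μ − 1 for per-cluster log₂ means; per-(subtype, cluster) overrides
  plant the TFH coexpression switch (LR: CXCL13 up/CXCR5 off; RLN and
  other CHL: the classical CXCR5⁺ profile); library-normalized +
  log₂(x+1). Default cohort: 8 samples per subtype, 400 cells per
  sample — sized so a two-digit number of cohort replicates runs in
  seconds while per-sample proportions still have small sampling error.
- **Survival**: exponential event times, hazard 0.05/year in the low
  group × hazard ratio 4 in the high group, administrative censoring at
  10 years, 60 cases split 50/50. Administrative-only censoring is the
  simplest mechanism sufficient for exercising KM/log-rank; the
  censoring pattern is non-informative by construction.

Not emulated: raw images, segmentation error, spectral bleed-through,
doublets, batch effects, cell-size features, informative censoring, or
spatial correlation beyond the planted rings. Passing tests on this
model therefore demonstrate the *estimators* are correct and calibrated,
not that real tissue meets the model's assumptions — on real exports,
gating thresholds and the rosette definition remain the analyst's
responsibility.

## Determinism and numerics

Every generator takes a seed and is bit-reproducible;
the pipeline fans one global seed out to stages via
`SeedSequence(seed, stage_index)` so skipping stages does not shift the
randomness of the rest. Writers prepend provenance headers (tool
version, parameter digest) and the pipeline manifest records a SHA-256
per output; identical (config, seed) runs produce identical hashes.
Undefined statistics are consistently NaN-with-flag, never zero.
Degenerate inputs (empty regions, zero-variance genes, all-censored
groups, empty margins) are either flagged or rejected with named
errors, as documented per function.

## Validation summary

The test suite asserts, among others: exact agreement of all spatial
statistics with brute-force scans (up to 1000 cells); exact recovery of
planted rosette fractions at zero noise and ≥95% sensitivity/specificity
at default noise; BH equal to the step-up definition on fuzzed
p-vectors; the exact rank-sum p for the 2-vs-2 worked example (1/3);
KM/log-rank equality with lifelines on random censored datasets;
log-rank type-I error within 0.05 ± 0.02 under a null hazard ratio; and
detection of the planted Treg depletion, CXCL13→CXCR5 interaction
ranking, and survival difference in ≥90–95% of simulated cohorts.
`scripts/acceptance.py` recomputes these rates from scratch at any seed.
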