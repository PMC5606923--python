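# Methods

This note records the statistical model, the defaults and the design
decisions behind `medipdmr`, and what the synthetic-data validation does and
does not establish.

## Count model and the exact window test

MeDIP-seq coverage in a fixed genomic window is treated as negative
binomial in the mean–dispersion parameterization, Var = μ + φμ², with a
single common dispersion φ shared by all windows; φ = 0 degenerates to
Poisson. This is the model family behind edgeR-style exact testing and is
the natural choice when replicate numbers are tiny (the motivating designs
have three pools per lineage), where per-window dispersion estimation is
hopeless.

The two-group window statistic is an exact conditional test. Library sizes
are first equalized by rescaling each sample's counts to the geometric-mean
library size (total-count factors; a trimmed TMM-style variant is available
behind a flag). This rescale-and-round step is a documented approximation —
exact conditioning is only defined at equal library sizes — playing the
role of edgeR's quantile adjustment. Group counts are then summed; a sum of
n i.i.d. NB(μ, φ) is NB(nμ, φ/n), the common per-sample mean is estimated
from the conditional total, and the two-sided p-value sums the conditional
probabilities of all splits whose probability does not exceed the observed
one, ties included (relative tie tolerance 10⁻¹⁰). At φ = 0 the conditional
distribution is exactly Binomial(t, n_a/(n_a+n_b)) and the test coincides
with the exact binomial test; the suite verifies both this and agreement
with an independent full-enumeration oracle to 10⁻⁸ for all totals ≤ 40.
Totals are enumerated exactly up to 2×10⁵; beyond that (far outside the
operating range) a Gaussian approximation of the conditional distribution
is used.

Two consequences of exactness are worth stating. First, the test is
conservative: P(p ≤ α) ≤ α, with the measured null rejection rate at
α = 0.05 around 0.050 under the default simulation. Second, the p-value
distribution is discrete — in particular the modal split always yields
p = 1, an atom of mass ≈ 0.02–0.03 at depth 30 with 6 vs 6 samples — so
null p-values are *not* Kolmogorov–Smirnov-uniform at large window counts,
and no ties-included exact test can be. Calibration should therefore be
judged by rejection rates and conservative validity, not KS uniformity.

Dispersion is a pooled method-of-moments estimate: over all windows of all
replicated groups, φ̂ solves Σ(v − c₁m) = φ̂ Σm² on library-normalized
counts (c₁ corrects the Poisson term for the normalization factors), floored
at zero. On simulated data with φ = 0.1 the estimate lands within
[0.05, 0.2] (typically ≈ 0.098); Poisson data gives ≈ 0. No empirical-Bayes
trending or tagwise shrinkage is attempted — a deliberate simplification
that keeps the estimator oracle-checkable.

## DMR calling

Seeds are windows with p strictly below the seed threshold. Edges extend
until no window with p < 0.1 lies within 1000 bp (inclusive) of the DMR
boundary, the gap measured between the boundary coordinate and the
candidate window's nearest edge; DMRs whose extensions touch or overlap are
merged. Implementation-wise this fixed point equals chaining consecutive
sub-0.1 windows whose gaps are all ≤ 1000 bp and keeping chains that
contain a seed — an equivalence the test-suite checks against a literal
rescan-to-fixed-point oracle on random landscapes and exhaustively on small
ones. A DMR's member windows are all result windows inside its coordinate
span (interior windows above 0.1 included); "significant windows" for the
multiple-window counts means members below the *seed* threshold. Direction
comes from the control share of summed normalized depth over significant
members: < 0.5 increase, > 0.5 decrease, exactly 0.5 flagged unchanged.
DMR names are `chrom:start` with a 1-based displayed start.

Because every seed threshold in use lies below the 0.1 extension level, the
extension/merging structure is threshold-independent, and tightening the
seed threshold can only delete DMRs — never split or create them. Sweep
tables over 10⁻⁴…10⁻¹¹ are therefore provably non-increasing. One
practical corollary: when sub-0.1 windows occur at a mean spacing near the
1000 bp reach (e.g. a fully dense landscape, where ~10% of null windows
fall below 0.1 and the mean gap between them is ~1 kb), chains percolate
and distinct signal regions merge into long spans. Planted-recovery
experiments therefore use planted regions separated by ≥ 2.5 kb, which is
also the realistic regime: real sperm DMR sets are orders of magnitude
sparser than that threshold.

No chromosome is excluded a priori from any stage.

## Clusters, overlaps, gene association

Cluster detection is deliberately the simplest defensible scan, since the
underlying studies name no method: fixed windows of span 5 Mb (default)
stepped by half a span, each window's DMR-midpoint count tested against
Binomial(n_total, span/genome length), BH correction across all scanned
windows, overlapping significant windows merged, and a reported cluster
must contain ≥ 2 DMRs. Under uniform placement the measured false-cluster
rate is ≈ 0.02 at α = 0.05 (BH makes the scan conservative).

Interval distance is zero on intersection, else the nearest-edge gap. Two
DMRs overlap when their flank-extended intervals intersect (flanks of 0,
1 kb or 10 kb in the generation-overlap analyses). Because interval overlap
is many-to-many, Venn counts depend on the counting unit; the report
carries per-set counts in both directions, with the first-listed set as the
headline unit. Gene association uses distance ≤ 10 kb (the promoter-scale
convention), reported per DMR and as the percentage of DMRs with at least
one gene.

## Signatures and the permutation null

A disease signature is the DMR set from case vs non-case individuals of the
exposed lineage at seed p < 10⁻⁵, the non-case side playing the control
role. Following the motivating design, the non-case group is cleaned of
animals carrying any other scored disease where the cohort supports it
(the CLI does this by default; `--any-noncase` disables it).

The null regroups the pooled case+non-case animals at random into two
groups of the original sizes, n_perm = 20 times, re-running the full
pipeline each time. Regroupings are drawn without replacement of label
vectors (distinct partitions, never the observed one). The empirical
p-value is the add-one estimator (1 + #{null ≥ observed})/(n_perm + 1), so
it can never be zero and beating all 20 permutations gives 1/21 ≈ 0.0476.
By default the common dispersion is estimated once from the observed
comparison and reused across permutations, which keeps observed and null
statistics on one model and makes the 21 runs share the p-value cache; a
flag re-estimates per draw. Note the null is conservative against strong
binary carrier structure: a random regrouping that happens to nearly
reconstruct the carrier split can recover much of the signature, so with
few animals the occasional null count approaches the observed one — the
add-one p then reports 2/21 rather than 1/21, which is honest behaviour,
not failure.

In-silico pooling sums member columns after optionally downsampling each
member to the smallest member total (the analogue of pooling equivalent
DNA amounts), then subsamples the pooled column to a target total with a
multivariate hypergeometric draw — totals are hit exactly and expected
window proportions preserved.

## Pathology rules

Disease calls: present iff the measure strictly exceeds the control mean
plus 2 sample SDs (strictly below mean − 2 SD for primordial follicle
loss). Lean/obese: control mean ∓ 1.5 SD on adipocyte area or BMI
(weight g / length cm²), strict at both cutoffs, boundary = normal; the
published fixed cutoffs (adipocyte area female 2671/3912, male 2425/3912
"μm"; BMI female 0.6040/0.7763, male 0.7894/0.9954 g/cm²) are provided as
constants and the upstream unit label is carried as given, although an area
would properly be μm². Adipocyte area averages the 20 largest cells per
image (5 images → 100 cells). Incidence tabulates animals with exactly one
vs ≥ 2 diseases (not-examined excluded per-category from denominators;
zero + single + multiple always equals the group size), compared with
two-sided Fisher's exact tests; continuous measures use pooled-variance
Student's t with a Welch flag. Sample (n−1) SDs are used everywhere —
control groups are small. The ≥2-of-3-observers consensus rule of the
histopathology protocol is an inter-rater procedure, out of computational
scope; per-observer counts enter the threshold rule directly.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the pipeline assumes:
a CpG-desert genome (Poisson CpG counts at 1.5/100 bp, with ~2% of windows
in island patches at 10/100 bp — densities chosen to put the modal window
at the desert rate); NB window counts at mean depth 30 reads/window,
φ = 0.1, with lognormal per-sample library factors at CV 0.2; planted DMRs
of 1–5 windows with multiplicative fold changes (control samples never
receive the fold); and cohorts whose linked phenotypes mark exactly the
planted-DMR carriers, enabling signature-recovery measurements against
ground truth. Defaults (2 × 2.5 Mb chromosomes = 5×10⁴ windows, 6 samples
per group) are the scaled-down study conditions used throughout the tests;
depth and dispersion are conventions, since the motivating work publishes
neither an effect-size nor a dispersion estimate for its real data.
Everything derives from one integer seed through named `SeedSequence`
sub-streams in a fixed order, so identical configurations are
byte-identical and each stage is independently reproducible.

Deliberately not modeled: read-level error and mapping, sonication
fragment-length variation (a fixed 300 bp extension stands in),
immunoprecipitation efficiency and CpG-density-dependent capture bias,
genomic mappability structure, and correlated dispersion across
neighbouring windows. Passing tests therefore demonstrate that the
*inference machinery* is correct and calibrated under its stated model —
not that the model captures every bias of real MeDIP-seq data; on real
data, CpG-coupling effects in particular can distort per-window means in
ways a common dispersion does not absorb.

## Numerical and interface choices

* Coordinates are 0-based half-open everywhere (BED convention); GFF3 gene
  input is converted on read.
* The final partial window of a chromosome is kept, flagged by its short
  length, so windows always cover the genome.
* Duplicate reads are retained (deduplication is upstream's concern);
  strand-less reads extend rightward.
* Seed-threshold comparison is strict (`p < threshold`), as is every
  pathology threshold; tie conventions are tested at the boundaries.
* Conditional p-values are cached on the rounded group-sum pair, group
  sizes and φ; permutation analyses deliberately reuse φ to exploit this.
* Run manifests carry parameters and the package version but no
  timestamps, so reruns are byte-comparable.
* Cluster-scan windows shorter than the span (short chromosomes, tails)
  are tested at their true width.

## Problem sizes used in validation

The default test and acceptance runs use 5×10⁴ windows for calibration and
planted-recovery experiments (100 planted 4-fold DMRs, 6 vs 6 at depth 30),
2×10⁴–3×10⁴ windows with 10–12 animals per lineage for signature/
permutation experiments, 10³ random landscapes plus an exhaustive 3¹²
pattern grid for the extension oracle, and exhaustive 2×2 tables with
totals ≤ 30 for Fisher's test. These sizes were chosen as the smallest at
which the measured rates are stable to well within the asserted margins.

## Known limitations

* Equivalence to any particular edgeR/MEDIPS version's numbers on real
  data is not claimed; the contracts are calibration and oracle
  equivalence of the stated model.
* The common-dispersion assumption and the rescale-and-round library
  equalization are approximations; both are documented above and bounded
  by the calibration tests.
* The binomial cluster scan tests marginal over-representation only; it
  does not model local mappability or CpG-density confounding.
* Exact-test p-values are discrete; downstream consumers should not treat
  them as continuous uniforms under the null (see the KS discussion above).
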