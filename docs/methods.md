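# Methods

This note documents the statistical model behind each pipeline stage, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical choices and known limitations.

## Input model

The pipeline consumes identification-engine exports: one row per
(lipid name, ion adduct) carrying a quality grade (A = class and all
fatty-acyl chains identified, B = class and some chains), a precursor
mass-accuracy value in ppm, and one peak-area column per LC-MS injection.
Lipid names follow shorthand nomenclature at two annotation levels:
molecular species (`TG 16:0_18:2_18:3`, underscore-separated chains, no
sn-position information) and sum composition (`TG 54:7`). Zero peak areas
are coerced to missing on ingestion: in this data type a zero is a
non-detection, not a measured quantity. No stage ever imputes values except
the single, flagged completion step before ordination.

## Preprocessing

Stages run in a fixed, enforced order; each filter only deletes rows and
never alters surviving values.

1. **Quality filter** — grades within an accepted set (default {A, B}) and
   |ppm| ≤ 5, matching the usual precursor search tolerance. Configurable.
2. **Adduct merge** — areas of the same species observed under different
   adducts are summed per injection. missing + x = x and
   missing + missing = missing, so total non-missing area is conserved.
3. **Technical-replicate averaging** — injections of the same biological
   sample are averaged (mean of non-missing). The aggregation scheme for
   technical replicates is a package choice; averaging before statistics
   keeps the biological replicate as the unit of inference.
4. **Blank exclusion** — a species is removed unless its mean biological
   intensity is at least 5-fold its mean blank intensity (species absent
   from blanks are kept). The mean over blank runs is used as the blank
   aggregate: symmetric and robust for the small number of blanks typical
   of these designs.
5. **Internal-standard normalization** — each species is divided, sample by
   sample, by its class's spiked standard; classes without their own
   standard resolve through a surrogate table (e.g. galactolipids via the
   DG standard). Proportional per-sample drifts cancel exactly. Standards
   are removed from the species axis afterwards.
6. **Median normalization** — sample *s* is scaled by
   reference / median(*s*), the reference being the median of per-sample
   medians; afterwards all per-sample medians are equal (the operation is
   idempotent).
7. **Presence filter** — a species must be detected in both growth sets
   and in ≥ 50 % of the samples of at least one condition. The 50 % rule is
   evaluated within condition × set cells rather than pooled across sets,
   because the two sets are independent experiments; this also makes the
   rule consistent with the exclusivity criterion below.

When the metadata carries a polarity column, each polarity is processed
independently end-to-end and the tables are unioned, keeping for shared
species the polarity with fewer missing values.

## Batch adjustment

The two growth sets are treated as batches and adjusted with ComBat in its
parametric empirical-Bayes form, on log₂ intensities, with the condition
indicator kept in the standardization design so condition signal is not
absorbed into batch means. Per-batch location (normal prior) and scale
(inverse-gamma prior) parameters are shrunk toward their across-species
means via the coupled posterior-mean iteration (convergence tolerance 1e-6,
maximum 1000 iterations — tighter than the Bioconductor reference's 1e-4,
which is why agreement with it is asserted at 1e-4). Species with zero
variance within every batch cannot be standardized; they are passed through
unadjusted and flagged on the fitted model object.

A property worth understanding: EB shrinkage deliberately does **not**
equalize per-species batch means. When every species carries the same true
shift δ, the species-to-species scatter of the observed batch means is
noise, the posterior means shrink onto the common δ, and each species
retains a noise-scale residual gap (≈ 0.2–0.4 log₂ units at replicate noise
0.8) even though the systematic δ is fully removed (mean residual across
species ≈ 0.02). Exact per-species equalization would require unshrunk
location/scale standardization, which overfits small batches. Planted
condition effects pass through undistorted: a log₂-fold of 1 under a batch
shift of 2 is recovered to within 1 % on average.

## PCA and contributions

Ordination uses the species detected in ≥ 50 % of **all** samples (a
different rule from the per-condition presence filter). Residual missing
values are completed by half the species' minimum observed value — the
common stand-in for below-detection-limit intensities; `zero` and
`row_median` are available and the completion count is recorded in the
provenance log. PCA is computed by SVD of the centered, per-species
unit-scaled log₂ matrix. Scaling is on by default so that high-abundance
classes (TGs) cannot dominate the decomposition purely by magnitude;
whether to scale is genuinely open in this kind of analysis, so it is
configurable off. The contribution of a species to a dimension is its
squared-loading share — the standard "contribution" of the ordination
literature — and the condition-separating dimension is the one maximizing
the absolute difference of condition score means.

## Enrichment

A species spans a dimension when its contribution strictly exceeds
`fold × 1/p` with fold = 2: more than twice the uniform expectation. Each
class with at least one member in the ordination universe is tested
one-vs-rest with the two-sided Fisher exact test. p-values are computed
with exact integer hypergeometric weights and the minimum-likelihood
two-sided rule (sum of all margin-consistent tables no more probable than
the observed one); integer comparison sidesteps floating-point tie
ambiguity entirely. The odds ratio is (a·d)/(b·c), infinite when b·c = 0.
Raw p-values are reported across classes — the enrichment answers one
question per class, and the class family is small; Benjamini–Hochberg
adjustment is available but off by default.

## Differential statistics

* **Exclusive species**: detected in ≥ 50 % of one condition's samples in
  at least one set and in zero samples of the other condition. The 50 %
  threshold mirrors the presence filter; "never detected opposite" makes
  the two exclusive sets disjoint by construction.
* **Double-bond profiles**: counts of distinct species per total
  double-bond number and condition (detection = at least one sample).
* **Acyl profiles**: the abundance of acyl *f* in sample *s* is the sum of
  values over molecular-level species containing *f*, counted once per
  species regardless of multiplicity — the profile counts species
  esterified with an acyl, not ester bonds. A multiplicity-weighted mode
  exists for bond-level questions. Sum-composition species cannot
  contribute and classes annotated only at that level are an error.
* **Multiple testing**: two-sided Welch t-tests on log₂ abundances
  (unequal variances assumed — no variance-homogeneity check is part of
  the protocol), Holm–Šídák-adjusted across the tested family, with stars
  at 0.05/0.01/0.001. Each group gets a Shapiro–Wilk flag; non-normal
  units are still tested but flagged, since no non-parametric fallback is
  part of the protocol. Units with fewer than two non-missing values per
  group, or no variance, are skipped and flagged. The two sets are pooled
  after batch adjustment rather than modeled as a factor.

## Synthetic-data generator

The generator emulates the study conditions: 2 sets × (9 control + 9
hypoxia) biological replicates × 2 technical injections, 3 extraction
blanks, and ~400 species whose class inventory puts glycerolipids +
glycerophospholipids at ~78 % of the total. Log₂ abundances are normal
around class baselines (TG 17, PC 16, PE 15, … — chosen to span the
realistic peak-area range) with species offsets (sd 1.5), replicate noise
(sd 0.8 log₂, i.e. roughly 60–75 % CV — deliberately on the conservative
end of biological variation), a per-sample global scale drift (sd 0.5,
cancelled by normalization), and injection noise (sd 0.15). Planted
effects: a log₂-fold of 0.6 on 60 % of TG species under hypoxia; 9 TG and
2 PE hypoxia-exclusive species, every one carrying a 16:4 fatty acyl (the
tri-acyl 16:3_16:4_18:2 TG among them); per-species batch shifts
N(1.0, 0.5) on the second set; logistic intensity-dependent dropout
(50 % missing at log₂ intensity 11, scale 1.5, ≈ 15 % missing overall);
~12 contaminant species whose blank level tracks their biological mean at
a 2-fold ratio (failing the 5-fold rule by construction); 30 % of species
split across two adduct rows; and a handful of grade-C junk rows. Minor
classes (LPC, SE, prenols) are emitted at sum-composition level, as
identification engines typically report them. Precursor-pool decreases
(DG/PC/LPC/MGDG down under stress) can be planted through
`condition_effects` but are not part of the default conditions.

What the generator does **not** emulate: retention-time structure,
isotopes, correlated co-elution artifacts, heavy-tailed or
species-correlated noise, condition-dependent dropout beyond what
intensity shifts induce, and class-correlated biological covariation.
Passing recovery tests therefore demonstrate that the pipeline's logic is
correct under its own statistical assumptions, not that real data meet
those assumptions.

## Problem sizes and determinism

Recovery properties are established by simulation at the design's native
scale (~400 species × 36 biological samples): 100 seeds for end-to-end
enrichment and exclusive-species recovery, 100 seeds for batch-adjustment
fold recovery (60 species × 36 samples), 1000 random-spanning resamples
for enrichment null calibration, and 1000 seeds of a 40-unit null family
for family-wise error control. All randomness flows from explicit integer
seeds; identical seeds give byte-identical outputs.

## Known limitations

* The condition-separating dimension is chosen by the score-gap heuristic;
  when the leading eigenvalues are nearly degenerate (the condition signal
  sits at the noise edge of a p ≫ n decomposition), the condition axis can
  rotate between two components and class enrichment may land on the
  dimension with the second-largest gap. Inspecting both reported
  dimensions' enrichment tables is advisable in marginal datasets.
* Exclusive species can at most reach 50 % overall detection in a balanced
  design, so they sit exactly at the ordination presence boundary; with
  any dropout a fraction of them is excluded from the PCA (they remain in
  the exclusivity analysis, which is condition-aware).
* Annotation stops at the molecular-species level: sn-positions,
  double-bond positions/geometry, and oxidized/ether species are outside
  the grammar and rejected explicitly rather than guessed at.
* The empirical-Bayes batch model assumes roughly normal log-intensities
  per batch; heavy contamination or bimodal species violate its priors and
  are better removed before adjustment.
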