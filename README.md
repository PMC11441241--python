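# lipidflow

Analysis pipeline for shotgun-lipidomics experiments that compare a
stressed condition against a control across two independently grown plant
sets (batches) — the design used to ask how waterlogging-induced root
hypoxia remodels the *Solanum lycopersicum* lipidome. It is written for
lipidomics practitioners who have per-lipid identification exports (one row
per lipid ion with per-injection peak areas) and want a reproducible route
from those tables to condition-exclusive species, class-enrichment
statistics, and fatty-acyl remodeling readouts.

## What it computes

**Preprocessing** (`lipidflow.preprocess`): grade/ppm quality filtering;
summing of adduct rows per species; exclusion of species whose mean
biological intensity is not ≥ 5× the mean blank-run intensity;
normalization to per-class spiked internal standards; median normalization
(every sample's median scaled to the median of medians); a presence filter
keeping species detected in both sets and in ≥ 50 % of the samples of at
least one condition.

**Ordination** (`lipidflow.reduction`): species detected in ≥ 50 % of all
samples are completed (half-minimum), batch-adjusted with parametric
empirical-Bayes ComBat (condition covariate preserved), and decomposed by
PCA on centered, unit-scaled log₂ intensities. The contribution of species
*i* to dimension *d* is its squared-loading share

&nbsp;&nbsp;&nbsp;&nbsp;*c*ᵢ𝒹 = *l*ᵢ𝒹² / Σⱼ *l*ⱼ𝒹².

**Enrichment** (`lipidflow.enrich`): species with *c*ᵢ𝒹 > 2/p (p = number
of species) "span" dimension *d*; each lipid class is tested
one-vs-rest for over-/under-representation among the spanning species of
the condition-separating dimension with the two-sided Fisher exact test
(minimum-likelihood rule, exact integer arithmetic).

**Differential statistics** (`lipidflow.differential`):
condition-exclusive species (detected in ≥ 50 % of one condition's samples
in at least one set, never in the other condition); double-bond histograms
per class; per-fatty-acyl abundance profiles; Welch t-tests on log₂
abundances with Holm–Šídák step-down correction,
adjⱼ = max over i ≤ j of (1 − (1 − p₍ᵢ₎)^(m − i + 1)).

**Synthetic data** (`lipidflow.synthdata`): a generator emulating the full
study design — 2 sets × (9 + 9) biological replicates × 2 injections,
~400 species across TG/DG/MGDG/DGDG/PA/PC/PE/LPC plus minor classes,
log-normal abundances, intensity-dependent dropout, batch shifts, blank
contamination, adduct splitting, internal standards, and planted hypoxia
effects (a TG increase and 16:4-carrying hypoxia-exclusive species) — with
a ground-truth object for parameter-recovery audits.

## Worked example

```python
from lipidflow import SyntheticConfig, generate, run_pipeline

ds = generate(SyntheticConfig(seed=1))
result = run_pipeline(ds.raw, ds.injections, ds.standards)
print(result.summary["n_species"])              # 394
print(result.summary["n_exclusive"])            # {'control': 0, 'hypoxia': 11}
print(result.summary["pct_glycero"])            # 79.7
print(result.enrichment[result.separating_dim].loc["TG"].round(4))
```

The last line prints the 2×2 Fisher table of TGs against the spanning
species of the separating dimension:

```
a                48
b                14
c                86
d               233
odds_ratio    9.289
p_value         0.0
direction  enriched
```

meaning 48 of the 62 species spanning the condition-separating dimension
are TGs (48 + 86 TGs in the ordination universe of 381 species), an odds
ratio of 9.3 with Fisher p ≈ 2 × 10⁻¹³ — the planted TG increase is what
separates hypoxia from control. All 11 planted hypoxia-exclusive species
(9 TGs and 2 PEs, each carrying a 16:4 fatty acyl) are recovered, and no
control-exclusive species is falsely reported.

The same pipeline runs from the command line:

```bash
lipidflow generate --seed 1 --out data/
lipidflow run --in data/ --out results/ --plot
lipidflow report results/ --out results/
```

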