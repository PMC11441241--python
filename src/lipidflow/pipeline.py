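"""End-to-end orchestration: raw records -> preprocessed table -> batch
adjustment + PCA -> class enrichment -> differential statistics."""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

import pandas as pd

from . import differential, enrich, preprocess, reduction
from .preprocess import DataError, IntensityTable, StandardMap

__all__ = ["RunConfig", "PipelineResult", "preprocess_table", "analyze",
           "run_pipeline"]


@dataclass
class RunConfig:
    """Stage parameters; defaults follow the documented pipeline rules."""

    grades: tuple[str, ...] = ("A", "B")
    max_ppm: float = 5.0
    blank_fold: float = 5.0
    presence_min_frac: float = 0.5
    require_both_sets: bool = True
    pca_min_frac: float = 0.5
    completion: str = "half_min"
    pca_dims: int = 2
    pca_scale: bool = True
    spanning_fold: float = 2.0
    alpha: float = 0.05
    treatment: str = "hypoxia"
    reference: str = "control"
    batch_key: str = "set_id"
    focus_class: str = "TG"

    def validate(self) -> None:
        if not self.grades:
            raise ValueError("grades must be nonempty")
        for name in ("presence_min_frac", "pca_min_frac"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.blank_fold <= 1:
            raise ValueError("blank_fold must exceed 1")
        if self.spanning_fold <= 0 or not 0 < self.alpha < 1:
            raise ValueError("spanning_fold must be > 0 and alpha in (0, 1)")

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


@dataclass
class PipelineResult:
    table: IntensityTable  # presence-filtered, per-sample
    pca_table: IntensityTable  # PCA-filtered, completed, batch-adjusted
    pca: reduction.PcaResult
    batch_model: reduction.BatchModel
    enrichment: dict[str, pd.DataFrame]  # per dimension
    separating_dim: str
    exclusives: dict[str, set[str]]
    double_bond: pd.DataFrame
    acyl_abundance: pd.DataFrame
    species_tests: pd.DataFrame
    acyl_tests: pd.DataFrame
    summary: dict = field(default_factory=dict)

    def write(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        self.table.values.to_csv(os.path.join(outdir, "intensities.tsv"), sep="\t")
        pd.DataFrame(self.table.log).to_csv(
            os.path.join(outdir, "filter_log.tsv"), sep="\t", index=False)
        self.pca.scores.to_csv(os.path.join(outdir, "pca_scores.tsv"), sep="\t")
        self.pca.loadings.to_csv(os.path.join(outdir, "pca_loadings.tsv"), sep="\t")
        self.pca.contributions.to_csv(
            os.path.join(outdir, "pca_contributions.tsv"), sep="\t")
        pd.DataFrame(
            {"explained_frac": self.pca.explained_frac},
            index=self.pca.scores.columns,
        ).to_csv(os.path.join(outdir, "pca_variance.tsv"), sep="\t")
        for dim, frame in self.enrichment.items():
            frame.to_csv(os.path.join(outdir, f"enrichment_{dim}.tsv"), sep="\t")
        self.double_bond.to_csv(os.path.join(outdir, "double_bonds.tsv"), sep="\t")
        self.acyl_abundance.to_csv(os.path.join(outdir, "acyl_abundance.tsv"),
                                   sep="\t")
        self.species_tests.to_csv(os.path.join(outdir, "species_tests.tsv"),
                                  sep="\t")
        self.acyl_tests.to_csv(os.path.join(outdir, "acyl_tests.tsv"), sep="\t")
        with open(os.path.join(outdir, "summary.json"), "w") as fh:
            json.dump(self.summary, fh, indent=2, default=str)


def _preprocess_one(
    records: pd.DataFrame,
    injections: pd.DataFrame,
    standards: StandardMap,
    config: RunConfig,
) -> IntensityTable:
    filtered = preprocess.quality_filter(records, set(config.grades),
                                         config.max_ppm)
    table = preprocess.merge_adducts(filtered, injections)
    table = preprocess.collapse_technical_replicates(table)
    table = preprocess.blank_filter(table, min_fold=config.blank_fold)
    table = preprocess.internal_standard_normalize(table, standards)
    table = preprocess.median_normalize(table)
    table = preprocess.presence_filter(
        table, config.presence_min_frac, config.require_both_sets)
    return table


def preprocess_table(
    records: pd.DataFrame,
    injections: pd.DataFrame,
    standards: StandardMap,
    config: RunConfig | None = None,
) -> IntensityTable:
    """Run the full preprocessing chain.

    When the metadata carries a ``polarity`` column with several levels,
    each polarity is processed independently end-to-end and the results are
    unioned; a species present in both keeps the polarity with fewer
    missing values.
    """
    config = config or RunConfig()
    config.validate()
    if "polarity" in injections.columns and injections["polarity"].nunique() > 1:
        tables = []
        for pol, meta in injections.groupby("polarity"):
            cols = ["name", "adduct", "grade", "ppm"] + list(meta.index)
            sub = records[[c for c in cols if c in records.columns]]
            tables.append(_preprocess_one(sub, meta, standards, config))
        base, rest = tables[0], tables[1:]
        values, species = base.values, dict(base.species)
        for other in rest:
            shared = values.index.intersection(other.values.index)
            prefer_other = [
                n for n in shared
                if other.values.loc[n].isna().sum() < values.loc[n].isna().sum()
            ]
            values.loc[prefer_other] = other.values.loc[prefer_other]
            new = other.values.index.difference(values.index)
            values = pd.concat([values, other.values.loc[new]])
            species.update({n: other.species[n] for n in new})
        out = base.advance("presence_filtered", values=values)
        out.species = species
        return out
    return _preprocess_one(records, injections, standards, config)


def analyze(table: IntensityTable, config: RunConfig | None = None
            ) -> PipelineResult:
    """Ordination, enrichment and differential statistics on a
    presence-filtered table."""
    config = config or RunConfig()
    config.validate()

    pca_table = reduction.pca_presence_filter(table, config.pca_min_frac)
    pca_table = reduction.complete_missing(pca_table, config.completion)
    pca_table, batch_model = reduction.batch_adjust(
        pca_table, batch_key=config.batch_key)
    pca = reduction.run_pca(pca_table, dims=config.pca_dims,
                            scale=config.pca_scale)
    sep_dim = reduction.separating_dimension(pca)

    enrichment = {}
    for dim in pca.scores.columns:
        spanning = enrich.spanning_species(pca, dim, config.spanning_fold)
        enrichment[dim] = enrich.class_enrichment(
            spanning, pca_table.species, alpha=config.alpha)

    exclusives = differential.exclusive_species(
        table, min_frac=config.presence_min_frac)
    dbp = differential.double_bond_profile(table, config.focus_class)
    try:
        acyl = differential.acyl_profile(table, config.focus_class)
    except DataError:
        acyl = pd.DataFrame()

    species_tests = differential.multi_ttest(
        pca_table, treatment=config.treatment, reference=config.reference)
    if not acyl.empty:
        # a zero acyl total means no contributing species was detected
        acyl_tests = differential.multi_ttest(
            acyl.replace(0.0, float("nan")), table.biological,
            treatment=config.treatment, reference=config.reference)
    else:
        acyl_tests = pd.DataFrame()

    categories = pd.Series(
        {n: sp.category for n, sp in table.species.items()})
    glycero = categories.isin(["glycerolipid", "glycerophospholipid"])
    summary = {
        "config_hash": config.digest(),
        "n_species": table.n_species,
        "n_species_pca": pca_table.n_species,
        "pct_glycero": round(100.0 * glycero.mean(), 1),
        "explained_pct": [round(100.0 * f, 1) for f in pca.explained_frac],
        "separating_dimension": sep_dim,
        "n_exclusive": {c: len(s) for c, s in exclusives.items()},
        "enrichment_separating_dim": enrichment[sep_dim]["direction"].to_dict(),
        "n_significant_species": int(
            (species_tests["p_adj"] < config.alpha).sum()),
    }
    return PipelineResult(
        table=table, pca_table=pca_table, pca=pca, batch_model=batch_model,
        enrichment=enrichment, separating_dim=sep_dim, exclusives=exclusives,
        double_bond=dbp, acyl_abundance=acyl, species_tests=species_tests,
        acyl_tests=acyl_tests, summary=summary,
    )


def run_pipeline(
    records: pd.DataFrame,
    injections: pd.DataFrame,
    standards: StandardMap,
    config: RunConfig | None = None,
) -> PipelineResult:
    """Preprocess then analyze; the convenience entry point."""
    config = config or RunConfig()
    table = preprocess_table(records, injections, standards, config)
    result = analyze(table, config)
    result.summary["stage_species_counts"] = _stage_counts(result.table)
    return result


def _stage_counts(table: IntensityTable) -> dict[str, int]:
    removed: dict[str, int] = {}
    for entry in table.log:
        if "species" in entry:
            removed[entry["stage"]] = removed.get(entry["stage"], 0) + 1
    return {"final": table.n_species, "removed_per_stage": removed}
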