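"""Raw identification exports -> clean, normalized, filtered intensity table.

The input contract mirrors a LipidSearch-style export: one row per
(lipid name, adduct) with a quality grade, a mass-accuracy (ppm) value and
one peak-area column per injection, plus a sample-metadata table and a
per-class internal-standard map.

The pipeline stages run in a fixed order:

    raw -> merged -> blank_filtered -> std_normalized
        -> median_normalized -> presence_filtered

Missing values are propagated, never imputed; filters delete rows but never
alter surviving values; adduct merging conserves the total non-missing area.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .nomenclature import LipidSpecies, parse_shorthand

__all__ = [
    "IntensityTable",
    "StandardMap",
    "PipelineError",
    "ConfigurationError",
    "DataError",
    "quality_filter",
    "merge_adducts",
    "collapse_technical_replicates",
    "blank_filter",
    "internal_standard_normalize",
    "median_normalize",
    "presence_filter",
]

#: canonical stage order; transitions may only move rightwards
STAGES = (
    "raw",
    "merged",
    "blank_filtered",
    "std_normalized",
    "median_normalized",
    "presence_filtered",
    "pca_filtered",
    "completed",
    "batch_adjusted",
)

DEFAULT_GRADES = frozenset({"A", "B"})
DEFAULT_MAX_PPM = 5.0  # matches the usual precursor search tolerance
DEFAULT_BLANK_FOLD = 5.0
DEFAULT_MIN_FRAC = 0.5

META_COLUMNS = ("sample_id", "condition", "set_id", "replicate", "is_blank")


class PipelineError(RuntimeError):
    pass


class ConfigurationError(PipelineError):
    pass


class DataError(PipelineError):
    pass


@dataclass
class StandardMap:
    """Per-class internal standard: ``class_code -> (standard row name, amount)``.

    ``surrogates`` maps classes without their own spiked standard to a
    donor class whose standard is used instead.
    """

    by_class: dict[str, str]
    amounts: dict[str, float] = field(default_factory=dict)
    surrogates: dict[str, str] = field(default_factory=dict)

    def standard_for(self, class_code: str) -> tuple[str, float]:
        code = class_code
        if code not in self.by_class and code in self.surrogates:
            code = self.surrogates[code]
        if code not in self.by_class:
            raise ConfigurationError(
                f"no internal standard mapped for lipid class {class_code!r}"
            )
        return self.by_class[code], self.amounts.get(code, 1.0)

    @property
    def standard_names(self) -> set[str]:
        return set(self.by_class.values())

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "StandardMap":
        """Build from a table with columns class_code, standard_name,
        amount and optional surrogate_of."""
        by_class, amounts, surrogates = {}, {}, {}
        for _, row in frame.iterrows():
            code = row["class_code"]
            surrogate = row.get("surrogate_of", "")
            if isinstance(surrogate, str) and surrogate:
                surrogates[code] = surrogate
            else:
                by_class[code] = row["standard_name"]
                amounts[code] = float(row.get("amount", 1.0))
        return cls(by_class, amounts, surrogates)


@dataclass
class IntensityTable:
    """Species x samples abundance matrix with metadata and provenance.

    ``values`` is indexed by canonical species name; columns are sample (or
    injection) ids matching ``samples.index``. ``species`` maps each row to
    its parsed :class:`LipidSpecies`. ``log`` accumulates machine-readable
    filter records across stages.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    species: dict[str, LipidSpecies]
    stage: str = "raw"
    log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.values.to_numpy(dtype=float, na_value=np.nan) < 0).any():
            raise DataError("negative intensities are not permitted")
        if list(self.values.columns) != list(self.samples.index):
            raise DataError("value columns do not match sample metadata index")

    # -- helpers -------------------------------------------------------
    @property
    def n_species(self) -> int:
        return self.values.shape[0]

    @property
    def biological(self) -> pd.DataFrame:
        """Metadata of non-blank samples."""
        return self.samples.loc[~self.samples["is_blank"].astype(bool)]

    def detected(self) -> pd.DataFrame:
        return self.values.notna()

    def advance(self, to_stage: str, **changes) -> "IntensityTable":
        """Return a copy at *to_stage*, enforcing forward-only transitions."""
        if STAGES.index(to_stage) < STAGES.index(self.stage):
            raise PipelineError(
                f"stage transition {self.stage!r} -> {to_stage!r} runs backwards"
            )
        out = replace(self, stage=to_stage, **changes)
        out.log = list(self.log)
        return out

    def record(self, **entry) -> None:
        self.log.append(entry)


def _parse_all(names: "pd.Series[str]") -> dict[str, LipidSpecies]:
    parsed: dict[str, LipidSpecies] = {}
    for i, name in names.items():
        try:
            sp = parse_shorthand(name)
        except Exception as exc:  # re-raise with row context
            raise DataError(f"row {i}: cannot parse lipid name {name!r}: {exc}")
        parsed[name] = sp
    return parsed


def quality_filter(
    records: pd.DataFrame,
    grades: frozenset[str] | set[str] = DEFAULT_GRADES,
    max_ppm: float = DEFAULT_MAX_PPM,
) -> pd.DataFrame:
    """Keep records with an accepted identification grade and |ppm| within
    the mass-accuracy tolerance."""
    if not grades:
        raise ConfigurationError("grade set must be nonempty")
    keep = records["grade"].isin(grades) & (records["ppm"].abs() <= max_ppm)
    return records.loc[keep].copy()


def merge_adducts(records: pd.DataFrame, samples: pd.DataFrame) -> IntensityTable:
    """Sum areas of identical lipids detected as different ion adducts.

    Zero areas are coerced to missing first (a zero peak area is a
    non-detection). missing + missing stays missing; missing + x = x, so the
    grand total of non-missing area is conserved.
    """
    area_cols = [c for c in records.columns if c in set(samples.index)]
    if not area_cols:
        raise DataError("no area columns matching the sample metadata")
    areas = records[area_cols].astype(float).replace(0.0, np.nan)
    by_raw_name = _parse_all(records["name"])
    canonical = records["name"].map(lambda n: by_raw_name[n].name)
    species = {sp.name: sp for sp in by_raw_name.values()}
    merged = areas.groupby(canonical).sum(min_count=1)
    merged = merged[list(samples.index)]
    return IntensityTable(merged, samples.copy(), species, stage="merged")


def collapse_technical_replicates(table: IntensityTable) -> IntensityTable:
    """Average technical injections per biological replicate.

    Requires a ``sample_id`` column in the metadata giving the biological
    sample each injection belongs to; the mean skips missing injections.
    """
    if "sample_id" not in table.samples.columns:
        return table
    groups = table.samples["sample_id"]
    values = table.values.T.groupby(groups).mean().T
    meta = (
        table.samples.groupby("sample_id", sort=False)
        .first()
        .loc[values.columns]
    )
    return table.advance("merged", values=values, samples=meta)


def blank_filter(
    table: IntensityTable,
    blanks: IntensityTable | None = None,
    min_fold: float = DEFAULT_BLANK_FOLD,
) -> IntensityTable:
    """Drop species not at least *min_fold*-fold above blank-run intensity.

    A species is retained when its mean blank intensity is missing or zero,
    or when mean biological intensity >= min_fold x mean blank intensity.
    The blank aggregate is the mean over blank runs (the rule's aggregate is
    a package choice; see the methods documentation).
    """
    if min_fold <= 1:
        raise ConfigurationError("min_fold must exceed 1")
    if blanks is None:
        is_blank = table.samples["is_blank"].astype(bool)
        blank_values = table.values.loc[:, is_blank[is_blank].index]
        bio_values = table.values.loc[:, is_blank[~is_blank].index]
        samples = table.samples.loc[~is_blank]
    else:
        blank_values = blanks.values.reindex(table.values.index)
        bio_values = table.values
        samples = table.samples

    blank_mean = blank_values.mean(axis=1, skipna=True)
    sample_mean = bio_values.mean(axis=1, skipna=True)
    clean_blank = blank_mean.isna() | (blank_mean == 0)
    ratio = sample_mean / blank_mean
    keep = clean_blank | (ratio >= min_fold)
    keep &= sample_mean.notna()

    out = table.advance(
        "blank_filtered", values=bio_values.loc[keep], samples=samples
    )
    out.species = {n: s for n, s in table.species.items() if n in out.values.index}
    for name in table.values.index[~keep]:
        out.record(
            stage="blank_filtered",
            species=name,
            rule=f"mean sample / mean blank < {min_fold}",
            statistic=float(ratio.get(name, np.nan)),
        )
    return out


def internal_standard_normalize(
    table: IntensityTable, standards: StandardMap
) -> IntensityTable:
    """Divide each species by its class's spiked internal standard, sample
    by sample, then drop the standard rows.

    Scale drifts common to a sample cancel; a class whose standard is
    missing from any sample is a hard error naming the samples.
    """
    values = table.values
    classes = {table.species[n].class_code for n in values.index
               if n not in standards.standard_names}
    std_rows: dict[str, str] = {}
    for code in sorted(classes):
        std_name, _ = standards.standard_for(code)
        if std_name not in values.index:
            raise ConfigurationError(
                f"standard {std_name!r} for class {code} absent from the table"
            )
        std_rows[code] = std_name
    for std_name in set(std_rows.values()):
        missing_in = values.columns[values.loc[std_name].isna()]
        if len(missing_in):
            raise DataError(
                f"standard {std_name!r} missing in samples: {list(missing_in)}"
            )

    keep = [n for n in values.index if n not in standards.standard_names]
    divisor = values.loc[[std_rows[table.species[n].class_code] for n in keep]]
    normalized = pd.DataFrame(
        values.loc[keep].to_numpy() / divisor.to_numpy(),
        index=keep,
        columns=values.columns,
    )
    amounts = pd.Series(
        {n: standards.standard_for(table.species[n].class_code)[1] for n in keep}
    )
    normalized = normalized.mul(amounts, axis=0)

    out = table.advance("std_normalized", values=normalized)
    out.species = {n: s for n, s in table.species.items() if n in normalized.index}
    return out


def median_normalize(table: IntensityTable) -> IntensityTable:
    """Equalize per-sample medians.

    Each sample is scaled by reference / own-median, where the reference is
    the median of the per-sample medians; afterwards every sample median
    equals the reference, and an already-equalized table is unchanged.
    """
    medians = table.values.median(axis=0, skipna=True)
    if medians.isna().any():
        bad = list(medians.index[medians.isna()])
        raise DataError(f"samples with no detected species: {bad}")
    reference = float(medians.median())
    factors = reference / medians
    return table.advance("median_normalized", values=table.values * factors)


def presence_filter(
    table: IntensityTable,
    min_frac: float = DEFAULT_MIN_FRAC,
    require_both_sets: bool = True,
) -> IntensityTable:
    """Keep species present in both growth sets and in >= *min_frac* of the
    samples of at least one condition."""
    meta = table.biological
    detected = table.values[meta.index].notna()

    # the 50 % rule is evaluated within condition x set cells: the two sets
    # are independent experiments, so detection rates are not pooled
    cond_ok = pd.Series(False, index=detected.index)
    for (_, _), sub in meta.groupby(["condition", "set_id"]):
        frac = detected[sub.index].sum(axis=1) / len(sub)
        cond_ok |= frac >= min_frac

    keep = cond_ok
    if require_both_sets:
        sets_ok = pd.Series(True, index=detected.index)
        for _, sub in meta.groupby("set_id"):
            sets_ok &= detected[sub.index].any(axis=1)
        keep = keep & sets_ok

    out = table.advance("presence_filtered", values=table.values.loc[keep])
    out.species = {n: s for n, s in table.species.items() if keep.get(n, False)}
    for name in table.values.index[~keep]:
        out.record(
            stage="presence_filtered",
            species=name,
            rule=f"both sets and >= {min_frac:.0%} of one condition",
            statistic=float(detected.loc[name].mean()),
        )
    return out
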