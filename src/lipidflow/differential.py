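"""Condition-exclusive species, double-bond/acyl profiles, and multiple
Welch t-tests with Holm–Šídák correction.

These are the per-species and aggregated statistics behind the lipid
remodeling readouts: which species appear only under hypoxia, how the
double-bond spectrum of a class shifts, which fatty acyls gain or lose
abundance, and which units change significantly (hypoxia vs control).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .nomenclature import MOLECULAR_SPECIES, FattyAcyl
from .preprocess import DataError, IntensityTable

__all__ = [
    "exclusive_species",
    "double_bond_profile",
    "acyl_profile",
    "normality_check",
    "holm_sidak",
    "multi_ttest",
    "significance_stars",
]


def exclusive_species(
    table: IntensityTable, min_frac: float = 0.5
) -> dict[str, set[str]]:
    """Species detected only under one condition.

    A species is exclusive to condition X when it is detected in at least
    *min_frac* of X samples in at least one set, and in zero samples of the
    other condition. The two exclusive sets are disjoint by construction.
    """
    meta = table.biological
    detected = table.values[meta.index].notna()
    conditions = list(pd.unique(meta["condition"]))
    if len(conditions) != 2:
        raise DataError(f"expected two conditions, got {conditions}")

    out: dict[str, set[str]] = {}
    for cond in conditions:
        other = [c for c in conditions if c != cond][0]
        own = meta.index[meta["condition"] == cond]
        others = meta.index[meta["condition"] == other]
        never_other = ~detected[others].any(axis=1)
        well_detected = pd.Series(False, index=detected.index)
        for _, sub in meta.loc[own].groupby("set_id"):
            frac = detected[sub.index].sum(axis=1) / len(sub)
            well_detected |= frac >= min_frac
        out[cond] = set(detected.index[never_other & well_detected])
    return out


def double_bond_profile(
    table: IntensityTable,
    class_code: str,
    detected_by_condition: dict[str, set[str]] | None = None,
) -> pd.DataFrame:
    """Count distinct species of one class per total double-bond number,
    separately per condition.

    A species counts for a condition when detected in at least one of its
    samples (or per an explicit ``detected_by_condition`` mapping). Bin
    totals per condition equal the number of species detected there.
    """
    members = [n for n, sp in table.species.items() if sp.class_code == class_code]
    meta = table.biological
    if detected_by_condition is None:
        detected = table.values[meta.index].notna()
        detected_by_condition = {
            cond: set(detected.index[detected[sub.index].any(axis=1)])
            for cond, sub in meta.groupby("condition")
        }
    conditions = sorted(detected_by_condition)
    dbs = sorted({table.species[n].sum_double_bonds for n in members})
    profile = pd.DataFrame(0, index=pd.Index(dbs, name="double_bonds"),
                           columns=conditions)
    for cond in conditions:
        for name in members:
            if name in detected_by_condition[cond]:
                profile.loc[table.species[name].sum_double_bonds, cond] += 1
    return profile


def acyl_profile(
    table: IntensityTable,
    class_code: str,
    weight_by_multiplicity: bool = False,
) -> pd.DataFrame:
    """Per-fatty-acyl abundance of one class, per sample.

    The abundance of acyl f in sample s is the sum over molecular-level
    species containing f of that species' value. By default a species with
    a repeated acyl (e.g. TG 16:0_18:2_18:2) contributes once to 18:2 —
    the profile counts species esterified with an acyl, not ester bonds;
    ``weight_by_multiplicity`` switches to bond-weighted sums.
    """
    members = [
        n
        for n, sp in table.species.items()
        if sp.class_code == class_code and sp.level == MOLECULAR_SPECIES
    ]
    if not members:
        raise DataError(
            f"class {class_code} has no molecular-species-level entries"
        )
    meta = table.biological
    values = table.values.loc[members, meta.index]
    acyls = sorted({c for n in members for c in table.species[n].chains})
    rows = {}
    for acyl in acyls:
        mult = np.array(
            [sum(1 for c in table.species[n].chains if c == acyl) for n in members]
        )
        w = mult if weight_by_multiplicity else (mult > 0).astype(int)
        rows[str(acyl)] = values.mul(w, axis=0).sum(axis=0, skipna=True)
    return pd.DataFrame(rows).T.rename_axis("acyl")


def normality_check(values: np.ndarray | pd.Series) -> tuple[float, float, bool]:
    """Shapiro–Wilk test; flag True when normality is not rejected (p > 0.05)."""
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 3:
        raise DataError(f"Shapiro–Wilk needs >= 3 values, got {x.size}")
    if np.ptp(x) == 0:
        raise DataError("Shapiro–Wilk undefined for constant input")
    w, p = stats.shapiro(x)
    return float(w), float(p), bool(p > 0.05)


def holm_sidak(p_values) -> np.ndarray:
    """Holm–Šídák step-down adjustment.

    Sorted ascending, adj_(i) = max_{j<=i} (1 - (1 - p_(j))^(m - j + 1)),
    clipped to 1, returned in the original order. Output is monotone in the
    sorted order and never below the input.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d vector of p-values")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    exponents = m - np.arange(m)
    adj = 1.0 - (1.0 - sorted_p) ** exponents
    adj = np.maximum.accumulate(adj)
    adj = np.clip(adj, 0.0, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class _Groups:
    hypoxia: pd.Index
    control: pd.Index


def _split(meta: pd.DataFrame, treatment: str, reference: str) -> _Groups:
    levels = set(meta["condition"])
    if {treatment, reference} - levels:
        raise DataError(
            f"conditions {treatment!r}/{reference!r} not both present in {sorted(levels)}"
        )
    return _Groups(
        hypoxia=meta.index[meta["condition"] == treatment],
        control=meta.index[meta["condition"] == reference],
    )


def multi_ttest(
    values: pd.DataFrame | IntensityTable,
    samples: pd.DataFrame | None = None,
    treatment: str = "hypoxia",
    reference: str = "control",
    log2_input: bool = False,
) -> pd.DataFrame:
    """Welch t-tests of every unit (row) treatment-vs-reference, with
    Holm–Šídák correction across the whole family.

    Accepts an :class:`IntensityTable` or any unit x sample abundance frame
    (e.g. an acyl profile) plus its sample metadata. Values are tested on
    the log2 scale; rows with fewer than two non-missing values per group,
    or no variance at all, are skipped and flagged (``tested = False``).
    Each group also gets a Shapiro–Wilk normality flag.
    """
    if isinstance(values, IntensityTable):
        samples = values.biological
        frame = values.values[samples.index]
    else:
        if samples is None:
            raise DataError("sample metadata required with a plain frame")
        samples = samples.loc[~samples["is_blank"].astype(bool)] \
            if "is_blank" in samples.columns else samples
        frame = values[samples.index]
    groups = _split(samples, treatment, reference)

    if not log2_input:
        arr = frame.to_numpy(dtype=float)
        if np.nanmin(arr) <= 0:
            raise DataError("abundances must be positive for the log2 scale")
        frame = np.log2(frame)

    rows = []
    for name, row in frame.iterrows():
        x = row[groups.hypoxia].dropna().to_numpy(dtype=float)
        y = row[groups.control].dropna().to_numpy(dtype=float)
        rec = {
            "unit": name,
            "n_treatment": x.size,
            "n_control": y.size,
            "tested": True,
        }
        pooled = np.concatenate([x, y])
        if x.size < 2 or y.size < 2 or np.ptp(pooled) == 0:
            rec.update(tested=False, log2_fold_change=np.nan, t_stat=np.nan,
                       p_raw=np.nan, normal_treatment=False, normal_control=False)
            rows.append(rec)
            continue
        t, p = stats.ttest_ind(x, y, equal_var=False)
        rec["log2_fold_change"] = float(x.mean() - y.mean())
        rec["t_stat"] = float(t)
        rec["p_raw"] = float(p)
        for label, g in (("normal_treatment", x), ("normal_control", y)):
            try:
                rec[label] = normality_check(g)[2]
            except DataError:
                rec[label] = False
        rows.append(rec)

    result = pd.DataFrame(rows).set_index("unit")
    result["p_adj"] = np.nan
    tested = result.index[result["tested"]]
    if len(tested):
        result.loc[tested, "p_adj"] = holm_sidak(result.loc[tested, "p_raw"])
    result["stars"] = [
        significance_stars(p) if np.isfinite(p) else "" for p in result["p_adj"]
    ]
    return result
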