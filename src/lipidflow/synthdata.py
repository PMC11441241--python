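"""Synthetic shotgun-lipidomics exports with known ground truth.

The generator emulates a two-set (batch), two-condition waterlogging
experiment on plant roots: nine biological replicates per condition per
set, two technical injections each, extraction blanks, one spiked internal
standard per lipid class, and a species inventory of roughly 400 lipids
dominated by glycerolipids and glycerophospholipids.

Abundances are log-normal with class-level baselines; hypoxia effects
(a TG increase, precursor-class decreases, hypoxia-exclusive species
carrying a 16:4 fatty acyl), multiplicative batch shifts, logistic
intensity-dependent dropout, blank contamination, and adduct-split rows
are planted and recorded in a :class:`GroundTruth` object so every
pipeline stage can be audited for parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nomenclature import LipidSpecies, load_vocabulary, parse_shorthand
from .preprocess import StandardMap

__all__ = ["SyntheticConfig", "GroundTruth", "SyntheticDataset", "generate",
           "truth_audit"]


def _default_species_per_class() -> dict[str, int]:
    # glycerolipids + glycerophospholipids ~78 % of the inventory
    return {
        "TG": 130, "DG": 30, "MGDG": 22, "DGDG": 19,
        "PA": 22, "PC": 35, "PE": 40, "LPC": 14,
        "Cer": 35, "SE": 33, "PR": 20,
    }


def _default_class_base() -> dict[str, float]:
    # log2 peak-area baselines; TGs are the abundant storage class
    return {
        "TG": 17.0, "DG": 14.0, "MGDG": 15.0, "DGDG": 14.0,
        "PA": 14.0, "PC": 16.0, "PE": 15.0, "LPC": 13.0,
        "Cer": 13.0, "SE": 13.0, "PR": 12.0,
    }


def _default_condition_effects() -> tuple[tuple[str, float, float], ...]:
    # (class, log2 fold hypoxia vs control, fraction of species affected):
    # the planted hypoxia signal is a TG rise on 60 % of TG species
    # (2^0.6 ~ 1.5-fold); precursor-pool decreases (DG/PC/LPC/MGDG) can be
    # added through this knob but are not part of the default conditions
    return (("TG", 0.6, 0.6),)


#: grammar-valid stand-ins for the per-class spiked standards; classes
#: without their own standard fall back to a surrogate class
STANDARD_NAMES = {
    "TG": "TG 15:0_15:0_18:1",
    "DG": "DG 15:0_18:1",
    "PC": "PC 15:0_18:1",
    "PE": "PE 15:0_18:1",
    "PA": "PA 15:0_18:1",
    "LPC": "LPC 18:1",
    "Cer": "Cer 15:0_18:1",
    "SE": "SE 18:1",
}
STANDARD_SURROGATES = {"MGDG": "DG", "DGDG": "DG", "PR": "SE"}

_ACYL_POOL = {
    "default": ["14:0", "15:0", "16:0", "16:1", "16:2", "16:3", "17:0",
                "18:0", "18:1", "18:2", "18:3", "18:4"],
    "TG": ["14:0", "15:0", "16:0", "16:1", "16:2", "16:3", "17:0", "18:0",
           "18:1", "18:2", "18:3", "18:4", "20:0", "20:1", "22:0"],
    "DG": ["16:0", "18:0", "18:1", "18:2", "18:3", "22:0", "24:0", "25:0",
           "26:0"],
    "Cer": ["16:0", "18:0", "18:1", "18:2", "20:0", "22:0", "22:1", "24:0",
            "24:1", "24:2", "26:0", "26:1"],
}

#: classes emitted at sum-composition level only (single-chain or minor
#: classes the identification engine reports as class + bulk composition);
#: (min_carbons, max_carbons, min_db, max_db)
_SUM_RANGES = {
    "LPC": (14, 26, 0, 4),
    "LPE": (14, 26, 0, 4),
    "SE": (14, 22, 0, 5),
    "PR": (35, 50, 2, 10),
    "CoQ": (35, 54, 4, 10),
}

_BULK_SPECIES = ("TG 54:7", "TG 54:8", "TG 52:5", "TG 52:6", "TG 53:5")
_NAMED_SPECIES = ("PC 18:1_18:2", "MGDG 18:2_18:2", "LPC 17:0", "LPC 18:2",
                  "DG 24:0_18:2", "DG 24:0_18:3", "DG 25:0_18:2",
                  "DG 26:0_18:2")
_NAMED_EXCLUSIVE = "TG 16:3_16:4_18:2"


@dataclass
class SyntheticConfig:
    """Study-design and noise parameters of the generator.

    The defaults are the emulated study conditions: 2 sets x (9 + 9)
    biological replicates x 2 technical injections, ~400 species with the
    planted hypoxia effects listed in ``condition_effects``, and 9 TG + 2 PE
    hypoxia-exclusive species carrying a 16:4 acyl.
    """

    seed: int = 0
    n_sets: int = 2
    n_reps: int = 9  # biological replicates per condition per set
    n_tech: int = 2  # technical injections per biological replicate
    n_blanks: int = 3
    species_per_class: dict[str, int] = field(
        default_factory=_default_species_per_class)
    class_base_log2: dict[str, float] = field(default_factory=_default_class_base)
    species_sd: float = 1.5  # between-species baseline spread (log2)
    noise_sd: float = 0.8  # biological replicate noise (log2)
    sample_scale_sd: float = 0.5  # per-sample global scale drift (log2)
    tech_sd: float = 0.15  # injection-to-injection noise (log2)
    condition_effects: tuple[tuple[str, float, float], ...] = field(
        default_factory=_default_condition_effects)
    n_exclusive_tg: int = 9
    n_exclusive_pe: int = 2
    exclusive_acyl: str = "16:4"
    exclusive_condition: str = "hypoxia"
    batch_log2_shift: float = 1.0  # mean set2-vs-set1 shift
    batch_shift_sd: float = 0.5
    dropout_midpoint: float | None = 11.0  # log2 intensity of 50 % dropout
    dropout_scale: float = 1.5
    n_contaminants: int = 12
    contamination_fold: float = 2.0  # sample/blank ratio of contaminants
    blank_noise_sd: float = 0.3
    adduct_split_prob: float = 0.3
    n_junk_rows: int = 15  # grade-C rows the quality filter must drop
    standard_log2: float = 14.0
    standard_sd: float = 0.1

    def validate(self) -> None:
        counts = [self.n_sets, self.n_reps, self.n_tech, self.n_blanks,
                  self.n_exclusive_tg, self.n_exclusive_pe,
                  self.n_contaminants, self.n_junk_rows]
        if any(c < 0 for c in counts):
            raise ValueError("counts must be >= 0")
        if self.n_sets < 1 or self.n_reps < 1 or self.n_tech < 1:
            raise ValueError("need >= 1 set, replicate and injection")
        for code, fold, frac in self.condition_effects:
            if not 0 <= frac <= 1:
                raise ValueError(f"effect fraction for {code} outside [0, 1]")
            if 2.0**fold <= 0:
                raise ValueError("fold must be positive on the linear scale")
        if self.contamination_fold <= 0:
            raise ValueError("contamination_fold must be > 0")
        vocab = load_vocabulary()
        unknown = set(self.species_per_class) - set(vocab)
        if unknown:
            raise ValueError(f"classes outside the vocabulary: {sorted(unknown)}")


@dataclass
class GroundTruth:
    """Planted effects, keyed by canonical species name."""

    species: pd.DataFrame  # class_code, category, log2_fold, exclusive_to,
    #                        is_contaminant, baseline_log2
    classes: pd.DataFrame  # planted_direction per class

    def exclusives(self, condition: str) -> set[str]:
        mask = self.species["exclusive_to"] == condition
        return set(self.species.index[mask])


@dataclass
class SyntheticDataset:
    raw: pd.DataFrame  # name, adduct, grade, ppm + one column per injection
    injections: pd.DataFrame  # metadata per injection column
    standards: StandardMap
    standards_frame: pd.DataFrame
    truth: GroundTruth
    config: SyntheticConfig

    def write(self, outdir) -> dict[str, str]:
        """Write the TSV dialects the preprocessing stage consumes."""
        import os

        os.makedirs(outdir, exist_ok=True)
        paths = {
            "records": os.path.join(outdir, "records.tsv"),
            "samples": os.path.join(outdir, "samples.tsv"),
            "standards": os.path.join(outdir, "standards.tsv"),
            "truth": os.path.join(outdir, "ground_truth.tsv"),
        }
        self.raw.to_csv(paths["records"], sep="\t", index=False)
        self.injections.to_csv(paths["samples"], sep="\t",
                               index_label="injection_id")
        self.standards_frame.to_csv(paths["standards"], sep="\t", index=False)
        self.truth.species.to_csv(paths["truth"], sep="\t", index_label="name")
        return paths


def _sample_chains(rng: np.random.Generator, class_code: str, n_chains: int
                   ) -> str | None:
    pool = _ACYL_POOL.get(class_code, _ACYL_POOL["default"])
    chains = sorted(
        rng.choice(pool, size=n_chains, replace=True),
        key=lambda s: tuple(int(x) for x in s.split(":")),
    )
    return f"{class_code} " + "_".join(chains)


def _build_inventory(config: SyntheticConfig, rng: np.random.Generator
                     ) -> list[LipidSpecies]:
    vocab = load_vocabulary()
    names: list[str] = []
    seen: set[str] = set()

    def add(name: str) -> None:
        sp = parse_shorthand(name)
        if sp.name not in seen:
            seen.add(sp.name)
            names.append(sp.name)

    for name in _BULK_SPECIES + _NAMED_SPECIES:
        if name.split()[0] in config.species_per_class:
            add(name)
    standard_names = {parse_shorthand(n).name for n in STANDARD_NAMES.values()}

    for code, target in config.species_per_class.items():
        _, n_chains = vocab[code]
        have = sum(1 for n in names if n.split()[0] == code)
        attempts = 0
        while have < target and attempts < 50 * target:
            attempts += 1
            if code in _SUM_RANGES:
                c_lo, c_hi, d_lo, d_hi = _SUM_RANGES[code]
                carbons = int(rng.integers(c_lo, c_hi + 1))
                dbs = int(rng.integers(d_lo, min(d_hi, carbons // 2) + 1))
                name = f"{code} {carbons}:{dbs}"
            else:
                name = _sample_chains(rng, code, n_chains)
            sp = parse_shorthand(name)
            if sp.name in seen or sp.name in standard_names:
                continue
            add(sp.name)
            have += 1
        if have < target:
            raise ValueError(
                f"acyl pool for {code} too small for {target} unique species"
            )
    return [parse_shorthand(n) for n in names]


def _exclusive_inventory(config: SyntheticConfig, rng: np.random.Generator,
                         existing: set[str]) -> list[str]:
    """Hypoxia-exclusive species, every one carrying the 16:4-type acyl."""
    out: list[str] = []
    if config.n_exclusive_tg > 0 and "TG" in config.species_per_class:
        out.append(parse_shorthand(_NAMED_EXCLUSIVE).name)
    pools = [("TG", config.n_exclusive_tg), ("PE", config.n_exclusive_pe)]
    vocab = load_vocabulary()
    for code, n_target in pools:
        if code not in config.species_per_class:
            continue
        _, n_chains = vocab[code]
        attempts = 0
        while sum(1 for n in out if n.startswith(code + " ")) < n_target \
                and attempts < 1000:
            attempts += 1
            partner_pool = ["16:3", "18:2", "18:3", "18:4", "16:0"]
            partners = list(rng.choice(partner_pool, size=n_chains - 1))
            chains = sorted(
                partners + [config.exclusive_acyl],
                key=lambda s: tuple(int(x) for x in s.split(":")),
            )
            name = f"{code} " + "_".join(chains)
            canon = parse_shorthand(name).name
            if canon not in existing and canon not in out:
                out.append(canon)
    return out


def generate(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """Emit raw records, blanks, standards, metadata and ground truth.

    Fully deterministic under ``config.seed``.
    """
    config = config or SyntheticConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    vocab = load_vocabulary()

    inventory = _build_inventory(config, rng)
    base_names = [sp.name for sp in inventory]
    exclusive = _exclusive_inventory(config, rng, set(base_names))
    all_names = base_names + exclusive
    species = {n: parse_shorthand(n) for n in all_names}
    n_species = len(all_names)

    # ---- sample layout ------------------------------------------------
    conditions = ("control", config.exclusive_condition)
    bio_rows = []
    for s in range(1, config.n_sets + 1):
        for cond in conditions:
            for r in range(1, config.n_reps + 1):
                bio_rows.append({
                    "sample_id": f"set{s}_{cond}_{r}",
                    "condition": cond, "set_id": f"set{s}",
                    "replicate": r, "is_blank": False,
                })
    for b in range(1, config.n_blanks + 1):
        bio_rows.append({
            "sample_id": f"blank_{b}", "condition": "blank",
            "set_id": f"set{1 + (b - 1) % config.n_sets}",
            "replicate": b, "is_blank": True,
        })
    bio = pd.DataFrame(bio_rows).set_index("sample_id")
    bio_ids = bio.index[~bio["is_blank"]]
    blank_ids = bio.index[bio["is_blank"]]

    # ---- planted per-species effects ---------------------------------
    base = np.array([
        config.class_base_log2.get(sp.class_code, 14.0) for sp in species.values()
    ])
    offsets = rng.normal(0.0, config.species_sd, n_species)
    folds = np.zeros(n_species)
    class_of = np.array([sp.class_code for sp in species.values()])
    planted_dir = {}
    for code, fold, frac in config.condition_effects:
        members = np.flatnonzero(class_of == code)
        members = np.array([i for i in members
                            if all_names[i] not in exclusive])
        n_hit = int(round(frac * len(members)))
        hit = rng.choice(members, size=n_hit, replace=False)
        folds[hit] = fold
        planted_dir[code] = "enriched" if fold > 0 else "depleted"
    batch_shift = rng.normal(config.batch_log2_shift, config.batch_shift_sd,
                             n_species)

    contaminant_pool = [i for i, n in enumerate(all_names)
                        if n not in exclusive and folds[i] == 0]
    contaminants = set(rng.choice(contaminant_pool,
                                  size=min(config.n_contaminants,
                                           len(contaminant_pool)),
                                  replace=False).tolist())

    # ---- biological intensity matrix (log2) ---------------------------
    sample_offset = pd.Series(
        rng.normal(0.0, config.sample_scale_sd, len(bio.index)), index=bio.index
    )
    is_hyp = (bio.loc[bio_ids, "condition"] == config.exclusive_condition
              ).to_numpy()
    is_set2plus = (bio.loc[bio_ids, "set_id"] != "set1").to_numpy()

    log2_int = (
        base[:, None]
        + offsets[:, None]
        + folds[:, None] * is_hyp[None, :]
        + batch_shift[:, None] * is_set2plus[None, :]
        + sample_offset[bio_ids].to_numpy()[None, :]
        + rng.normal(0.0, config.noise_sd, (n_species, len(bio_ids)))
    )

    missing = np.zeros_like(log2_int, dtype=bool)
    if config.dropout_midpoint is not None:
        p_miss = 1.0 / (1.0 + np.exp(
            (log2_int - config.dropout_midpoint) / config.dropout_scale))
        missing = rng.random(log2_int.shape) < p_miss
    for i, name in enumerate(all_names):
        if name in exclusive:
            missing[i, ~is_hyp] = True

    values = pd.DataFrame(
        np.where(missing, np.nan, 2.0**log2_int), index=all_names,
        columns=bio_ids,
    )

    # ---- blanks -------------------------------------------------------
    blank_vals = pd.DataFrame(np.nan, index=all_names, columns=blank_ids)
    for i in contaminants:
        # anchor the blank level to the realized biological mean so the
        # sample/blank ratio really sits at contamination_fold
        bio_mean = np.nanmean(values.iloc[i].to_numpy())
        lvl = (np.log2(bio_mean) - np.log2(config.contamination_fold)
               + rng.normal(0.0, config.blank_noise_sd, len(blank_ids)))
        blank_vals.iloc[i] = 2.0**lvl

    # ---- standards ----------------------------------------------------
    std_map = StandardMap(
        by_class={c: parse_shorthand(n).name for c, n in STANDARD_NAMES.items()
                  if c in config.species_per_class
                  or c in STANDARD_SURROGATES.values()},
        amounts={},
        surrogates={c: s for c, s in STANDARD_SURROGATES.items()
                    if c in config.species_per_class},
    )
    std_rows = {}
    for code, std_name in std_map.by_class.items():
        lvl = (config.standard_log2 + sample_offset[bio_ids].to_numpy()
               + rng.normal(0.0, config.standard_sd, len(bio_ids)))
        std_rows[std_name] = 2.0**lvl
    std_values = pd.DataFrame(std_rows).T
    std_values.columns = bio_ids

    # ---- expand to injections and adduct rows ------------------------
    inj_rows = []
    for sid, row in bio.iterrows():
        reps = 1 if row["is_blank"] else config.n_tech
        for t in range(1, reps + 1):
            inj_rows.append({
                "injection_id": f"{sid}_t{t}", "sample_id": sid,
                "condition": row["condition"], "set_id": row["set_id"],
                "replicate": row["replicate"], "is_blank": row["is_blank"],
            })
    injections = pd.DataFrame(inj_rows).set_index("injection_id")

    def to_injections(frame: pd.DataFrame) -> pd.DataFrame:
        cols = {}
        for inj, meta in injections.iterrows():
            sid = meta["sample_id"]
            if sid in frame.columns:
                noise = 2.0 ** rng.normal(0.0, config.tech_sd, len(frame))
                cols[inj] = frame[sid].to_numpy() * noise
            else:
                cols[inj] = np.full(len(frame), np.nan)
        return pd.DataFrame(cols, index=frame.index)

    full = pd.concat([values, std_values])
    full_blank = pd.concat(
        [blank_vals,
         pd.DataFrame(np.nan, index=std_values.index, columns=blank_ids)]
    )
    inj_bio = to_injections(full)
    inj_blank = to_injections(full_blank)
    matrix = inj_bio.combine_first(inj_blank)[injections.index]

    primary_adduct = {"glycerolipid": "+NH4", "glycerophospholipid": "+H",
                      "sphingolipid": "+H", "sterol lipid": "+NH4",
                      "prenol lipid": "+H"}
    records = []
    for name in matrix.index:
        sp = species.get(name) or parse_shorthand(name)
        areas = matrix.loc[name]
        adduct = primary_adduct[vocab[sp.class_code][0]]
        split = (name in values.index) and (rng.random() < config.adduct_split_prob)
        ppm = float(np.clip(rng.normal(0.0, 1.5), -4.5, 4.5))
        grade = "A" if rng.random() < 0.7 else "B"
        if split:
            frac = rng.uniform(0.55, 0.9)
            f = np.clip(frac + rng.normal(0.0, 0.05, len(areas)), 0.05, 0.95)
            records.append({"name": name, "adduct": adduct, "grade": grade,
                            "ppm": ppm, **dict(zip(areas.index, areas * f))})
            records.append({"name": name, "adduct": "+Na", "grade": grade,
                            "ppm": float(np.clip(rng.normal(0.0, 1.5), -4.5, 4.5)),
                            **dict(zip(areas.index, areas * (1 - f)))})
        else:
            records.append({"name": name, "adduct": adduct, "grade": grade,
                            "ppm": ppm, **dict(zip(areas.index, areas))})
    # low-grade junk the quality filter must remove
    junk_names = rng.choice(np.array(all_names), size=config.n_junk_rows)
    for name in junk_names:
        areas = rng.uniform(10.0, 100.0, len(matrix.columns))
        records.append({"name": str(name), "adduct": "+Na", "grade": "C",
                        "ppm": float(rng.normal(0.0, 4.0)),
                        **dict(zip(matrix.columns, areas))})
    raw = pd.DataFrame(records)

    # ---- ground truth -------------------------------------------------
    truth_species = pd.DataFrame({
        "class_code": [species[n].class_code for n in all_names],
        "category": [species[n].category for n in all_names],
        "log2_fold": folds,
        "exclusive_to": [config.exclusive_condition if n in exclusive else ""
                         for n in all_names],
        "is_contaminant": [i in contaminants for i in range(n_species)],
        "baseline_log2": base + offsets,
        "batch_log2_shift": batch_shift,
    }, index=pd.Index(all_names, name="name"))
    truth_classes = pd.DataFrame({
        "planted_direction": [planted_dir.get(c, "none")
                              for c in sorted(set(class_of))],
    }, index=pd.Index(sorted(set(class_of)), name="class_code"))
    truth = GroundTruth(truth_species, truth_classes)

    std_frame = pd.DataFrame(
        [{"class_code": c, "standard_name": n, "amount": 1.0,
          "surrogate_of": ""} for c, n in std_map.by_class.items()]
        + [{"class_code": c, "standard_name": "", "amount": "",
            "surrogate_of": s} for c, s in std_map.surrogates.items()]
    )
    return SyntheticDataset(raw, injections, std_map, std_frame, truth, config)


def truth_audit(results: dict, truth: GroundTruth) -> dict:
    """Score pipeline outputs against the planted truth.

    *results* may carry ``exclusives`` (condition -> set of names),
    ``enrichment`` (class-level frame with a ``direction`` column) and
    ``fold_estimates`` (log2 fold per species). Unknown species names are a
    universe-mismatch error.
    """
    report: dict = {}
    known = set(truth.species.index)

    if "exclusives" in results:
        for cond, found in results["exclusives"].items():
            unknown = set(found) - known
            if unknown:
                raise ValueError(
                    f"species outside the truth universe: {sorted(unknown)[:5]}")
            true_set = truth.exclusives(cond)
            tp = len(found & true_set)
            fp = len(found - true_set)
            fn = len(true_set - found)
            tn = len(known) - tp - fp - fn
            report[f"exclusive_{cond}"] = {
                "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
                "specificity": tn / (tn + fp) if tn + fp else float("nan"),
                "precision": tp / (tp + fp) if tp + fp else float("nan"),
                "tp": tp, "fp": fp, "fn": fn,
            }

    if "fold_estimates" in results:
        est = results["fold_estimates"]
        unknown = set(est.index) - known
        if unknown:
            raise ValueError(
                f"species outside the truth universe: {sorted(unknown)[:5]}")
        planted = truth.species.loc[est.index, "log2_fold"]
        nonzero = planted != 0
        if nonzero.any():
            report["fold_sign_accuracy"] = float(
                (np.sign(est[nonzero]) == np.sign(planted[nonzero])).mean())

    if "enrichment" in results:
        frame = results["enrichment"]
        hits = {}
        for code, row in frame.iterrows():
            want = truth.classes["planted_direction"].get(code, "none")
            hits[code] = {"planted": want, "observed": row["direction"],
                          "hit": want == row["direction"]}
        report["enrichment"] = hits
    return report
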