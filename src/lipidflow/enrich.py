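"""Class enrichment among PCA-dimension-spanning lipid species.

A species "spans" a dimension when its contribution exceeds twice (by
default) the uniform expectation 1/p, p being the number of species in the
ordination. Each lipid class is then tested for over-/under-representation
among the spanning species with the two-sided Fisher exact test
(minimum-likelihood method): this is how a TG-driven separation of the
conditions becomes a single enrichment statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .nomenclature import LipidSpecies
from .reduction import PcaResult

__all__ = [
    "EnrichmentResult",
    "spanning_species",
    "fisher_exact",
    "class_enrichment",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """2x2 Fisher test of one lipid class vs the spanning/non-spanning split.

    a = spanning & class, b = spanning & other,
    c = non-spanning & class, d = non-spanning & other.
    """

    class_code: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p_value: float
    direction: str  # enriched / depleted / none


def spanning_species(
    pca: PcaResult, dim: str | int, fold: float = 2.0
) -> set[str]:
    """Species whose contribution to *dim* strictly exceeds fold x (1/p)."""
    if isinstance(dim, int):
        dim = f"dim{dim}"
    contrib = pca.contributions[dim]
    p = len(contrib)
    threshold = fold / p
    return set(contrib.index[contrib > threshold])


def fisher_exact(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher exact test on the 2x2 table [[a, b], [c, d]].

    p is the sum of hypergeometric probabilities, over all tables with the
    observed margins, that do not exceed the observed table's probability
    (minimum-likelihood two-sided rule). The odds ratio is (a*d)/(b*c),
    infinity when b*c = 0.
    """
    counts = (a, b, c, d)
    if any(x < 0 for x in counts):
        raise ValueError(f"negative count in table {counts}")
    if not all(float(x).is_integer() for x in counts):
        raise ValueError(f"non-integer count in table {counts}")
    n = a + b + c + d
    if n == 0:
        raise ValueError("empty table")
    a, b, c, d = (int(x) for x in counts)
    row1, col1 = a + b, a + c
    # integer-weight hypergeometric pmf: weight(x) = C(col1,x)*C(n-col1,row1-x),
    # common denominator C(n,row1); exact integer comparison avoids
    # floating-point tie ambiguity in the minimum-likelihood rule
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    weights = {
        x: math.comb(col1, x) * math.comb(n - col1, row1 - x)
        for x in range(lo, hi + 1)
    }
    w_obs = weights[a]
    total = math.comb(n, row1)
    p = sum(w for w in weights.values() if w <= w_obs) / total
    p = min(float(p), 1.0)
    odds = math.inf if b * c == 0 else (a * d) / (b * c)
    return odds, p


def class_enrichment(
    spanning: set[str],
    universe: dict[str, LipidSpecies],
    by: str = "class_code",
    alpha: float = 0.05,
    adjust: bool = False,
) -> pd.DataFrame:
    """Fisher-test every lipid class (or category) one-vs-rest against the
    spanning set.

    *universe* maps species name -> parsed species for every species in the
    PCA; *spanning* must be a subset of its keys. Raw Fisher p-values are
    reported; Benjamini–Hochberg adjustment across classes is available but
    off by default.
    """
    unknown = spanning - set(universe)
    if unknown:
        raise ValueError(f"spanning species outside the universe: {sorted(unknown)[:5]}")
    labels = {name: getattr(sp, by) for name, sp in universe.items()}
    classes = sorted(set(labels.values()))
    n_total, n_span = len(universe), len(spanning)

    rows = []
    for code in classes:
        members = {n for n, lab in labels.items() if lab == code}
        a = len(members & spanning)
        b = n_span - a
        c = len(members) - a
        d = n_total - a - b - c
        odds, p = fisher_exact(a, b, c, d)
        rows.append(
            EnrichmentResult(code, a, b, c, d, odds, p, direction="none")
        )

    frame = pd.DataFrame([r.__dict__ for r in rows]).set_index("class_code")
    p_for_call = frame["p_value"]
    if adjust:
        from statsmodels.stats.multitest import multipletests

        p_for_call = pd.Series(
            multipletests(frame["p_value"], method="fdr_bh")[1],
            index=frame.index,
        )
        frame["p_adjusted"] = p_for_call
    sig = p_for_call < alpha
    frame.loc[sig & (frame["odds_ratio"] > 1), "direction"] = "enriched"
    frame.loc[sig & (frame["odds_ratio"] < 1), "direction"] = "depleted"
    return frame
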