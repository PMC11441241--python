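"""Batch adjustment and principal component analysis of the lipidome.

The two growth sets are independent experiments, so set-to-set
(batch) location/scale differences are removed with the parametric
empirical-Bayes ComBat procedure before ordination, while the
control/hypoxia contrast is preserved in the standardization design.

PCA is computed on log2 intensities, centered and (by default) unit-scaled
per species so high-abundance classes cannot dominate purely by magnitude.
Each species' "contribution" to a dimension is its squared-loading share,
the standard definition from the ordination literature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .preprocess import ConfigurationError, DataError, IntensityTable

__all__ = [
    "PcaResult",
    "BatchModel",
    "pca_presence_filter",
    "complete_missing",
    "batch_adjust",
    "combat",
    "run_pca",
    "separating_dimension",
]


def pca_presence_filter(
    table: IntensityTable, min_frac: float = 0.5
) -> IntensityTable:
    """Keep species detected in at least *min_frac* of ALL biological samples.

    This is deliberately a different rule from the per-condition presence
    filter used for species counting: ordination uses the species matrix
    that is broadly observed across the whole sample set.
    """
    meta = table.biological
    frac = table.values[meta.index].notna().sum(axis=1) / len(meta.index)
    keep = frac >= min_frac
    out = table.advance("pca_filtered", values=table.values.loc[keep])
    out.species = {n: s for n, s in table.species.items() if keep.get(n, False)}
    for name in table.values.index[~keep]:
        out.record(
            stage="pca_filtered",
            species=name,
            rule=f"detected in >= {min_frac:.0%} of all samples",
            statistic=float(frac.loc[name]),
        )
    return out


def complete_missing(
    table: IntensityTable, method: str = "half_min"
) -> IntensityTable:
    """Fill residual missing values so downstream matrix methods can run.

    half_min (default): half the species' minimum observed value — the
    usual lipidomics stand-in for below-detection-limit intensities.
    Alternatives: ``zero``, ``row_median``. Completion is recorded in the
    table log; it is the only place the pipeline fills values.
    """
    values = table.values.copy()
    n_filled = int(values.isna().to_numpy().sum())
    if method == "half_min":
        fill = values.min(axis=1, skipna=True) / 2.0
        values = values.T.fillna(fill).T
    elif method == "zero":
        values = values.fillna(0.0)
    elif method == "row_median":
        fill = values.median(axis=1, skipna=True)
        values = values.T.fillna(fill).T
    else:
        raise ConfigurationError(f"unknown completion method {method!r}")
    if values.isna().any().any():
        raise DataError("completion left missing values (all-missing species?)")
    out = table.advance("completed", values=values)
    out.record(stage="completed", rule=f"missing completed by {method}",
               statistic=n_filled)
    return out


@dataclass
class BatchModel:
    """Fitted empirical-Bayes batch model (log2 scale)."""

    batches: list[str]
    gamma_star: pd.DataFrame  # species x batch additive shifts
    delta_star: pd.DataFrame  # species x batch variance factors
    hyperparameters: dict[str, dict[str, float]]
    unadjusted: list[str] = field(default_factory=list)  # zero-variance species


def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (2 * s2 + m**2) / s2


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (m * s2 + m**3) / s2


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(sum2, n, a, b):
    return (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)


def _it_sol(z, g_hat, d_hat, g_bar, t2, a, b, tol=1e-6, max_iter=1000):
    """Iterate the coupled posterior means for one batch (parametric EB)."""
    n = (~np.isnan(z)).sum(axis=1).astype(float)
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        g_new = _postmean(g_hat, g_bar, n, d_old, t2)
        sum2 = np.nansum((z - g_new[:, None]) ** 2, axis=1)
        d_new = _postvar(sum2, n, a, b)
        change = max(
            np.max(np.abs(g_new - g_old) / np.abs(g_old).clip(min=1e-12)),
            np.max(np.abs(d_new - d_old) / np.abs(d_old).clip(min=1e-12)),
        )
        g_old, d_old = g_new, d_new
        if change < tol:
            break
    return g_old, d_old


def combat(
    data: pd.DataFrame,
    batch: pd.Series,
    covariates: pd.DataFrame | None = None,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> tuple[pd.DataFrame, BatchModel]:
    """Parametric empirical-Bayes location/scale batch adjustment.

    *data* is features x samples on an additive (log) scale; *batch* labels
    the samples; *covariates* (e.g. the condition indicator) are kept in the
    standardization design so biological signal is not absorbed into the
    batch means. Features with zero variance within every batch cannot be
    standardized and are passed through unadjusted (flagged in the model).
    """
    X = data.to_numpy(dtype=float)
    batch = batch.loc[data.columns]
    levels = list(pd.unique(batch))
    n_array = np.array([(batch == b).sum() for b in levels], dtype=float)
    if (n_array < 2).any():
        raise DataError("every batch needs >= 2 samples")
    if len(levels) == 1:
        model = BatchModel(levels,
                           pd.DataFrame(0.0, index=data.index, columns=levels),
                           pd.DataFrame(1.0, index=data.index, columns=levels),
                           {})
        return data.copy(), model

    batch_design = np.column_stack([(batch == b).to_numpy(float) for b in levels])
    design = batch_design
    if covariates is not None:
        cov = pd.get_dummies(covariates.loc[data.columns], drop_first=True)
        design = np.column_stack([batch_design, cov.to_numpy(float)])

    n_samples = X.shape[1]
    # per-feature OLS of the full design
    B_hat = np.linalg.solve(design.T @ design, design.T @ X.T)
    grand_mean = (n_array / n_samples) @ B_hat[: len(levels)]
    resid = X - (design @ B_hat).T
    var_pooled = (resid**2).mean(axis=1)

    degenerate = var_pooled <= 0
    ok = ~degenerate
    stand_mean = grand_mean[:, None] * np.ones((1, n_samples))
    if covariates is not None:
        tmp = design.copy()
        tmp[:, : len(levels)] = 0
        stand_mean = stand_mean + (tmp @ B_hat).T
    sd = np.sqrt(var_pooled[ok])[:, None]
    Z = (X[ok] - stand_mean[ok]) / sd

    gamma_hat = np.linalg.solve(
        batch_design.T @ batch_design, batch_design.T @ Z.T
    )  # batches x features
    delta_hat = np.vstack(
        [Z[:, (batch == b).to_numpy()].var(axis=1, ddof=1) for b in levels]
    )
    gamma_bar, t2 = gamma_hat.mean(axis=1), gamma_hat.var(axis=1, ddof=1)

    gamma_star = np.empty_like(gamma_hat)
    delta_star = np.empty_like(delta_hat)
    hyper: dict[str, dict[str, float]] = {}
    for i, b in enumerate(levels):
        a_pr, b_pr = _aprior(delta_hat[i]), _bprior(delta_hat[i])
        mask = (batch == b).to_numpy()
        g, d = _it_sol(
            Z[:, mask], gamma_hat[i], delta_hat[i], gamma_bar[i], t2[i],
            a_pr, b_pr, tol=tol, max_iter=max_iter,
        )
        gamma_star[i], delta_star[i] = g, d
        hyper[str(b)] = {
            "gamma_bar": float(gamma_bar[i]), "tau2": float(t2[i]),
            "a_prior": float(a_pr), "b_prior": float(b_pr),
        }

    adjusted = Z.copy()
    for i, b in enumerate(levels):
        mask = (batch == b).to_numpy()
        adjusted[:, mask] = (
            Z[:, mask] - gamma_star[i][:, None]
        ) / np.sqrt(delta_star[i])[:, None]
    X_out = X.copy()
    X_out[ok] = adjusted * sd + stand_mean[ok]

    idx = data.index
    g_frame = pd.DataFrame(0.0, index=idx, columns=levels)
    d_frame = pd.DataFrame(1.0, index=idx, columns=levels)
    g_frame.loc[idx[ok]] = gamma_star.T
    d_frame.loc[idx[ok]] = delta_star.T
    model = BatchModel(
        [str(b) for b in levels], g_frame, d_frame, hyper,
        unadjusted=[str(i) for i in idx[degenerate]],
    )
    return pd.DataFrame(X_out, index=idx, columns=data.columns), model


def batch_adjust(
    table: IntensityTable,
    batch_key: str = "set_id",
    covariate: str = "condition",
) -> tuple[IntensityTable, BatchModel]:
    """ComBat-adjust an intensity table across growth sets.

    Intensities are log2-transformed internally (they must be positive and
    complete — run :func:`complete_missing` first), adjusted, and
    back-transformed, so sample and species counts are unchanged.
    """
    if table.values.isna().any().any():
        raise DataError("batch adjustment needs a complete matrix; "
                        "run complete_missing first")
    if (table.values.to_numpy() <= 0).any():
        raise DataError("batch adjustment needs strictly positive intensities")
    meta = table.biological
    log2 = np.log2(table.values[meta.index])
    adjusted, model = combat(
        log2, meta[batch_key], covariates=meta[[covariate]]
    )
    out = table.advance("batch_adjusted", values=2.0**adjusted,
                        samples=meta.copy())
    return out, model


@dataclass
class PcaResult:
    """PCA of the (log2, standardized) lipidome.

    loadings have unit-norm columns; contributions are squared-loading
    shares, each column summing to 1.
    """

    scores: pd.DataFrame  # samples x dims
    loadings: pd.DataFrame  # species x dims
    explained_frac: np.ndarray
    contributions: pd.DataFrame  # species x dims
    samples: pd.DataFrame

    @property
    def n_species(self) -> int:
        return self.loadings.shape[0]


def run_pca(
    table: IntensityTable, dims: int = 2, scale: bool = True
) -> PcaResult:
    """PCA of log2 intensities, centered (and unit-scaled) per species."""
    if table.values.isna().any().any():
        raise DataError("PCA needs a complete matrix; run complete_missing first")
    meta = table.biological
    X = np.log2(table.values[meta.index].to_numpy(dtype=float)).T  # samples x species
    rank = min(X.shape[0] - 1, X.shape[1])
    if dims > rank:
        raise ConfigurationError(f"dims={dims} exceeds the matrix rank {rank}")
    X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=0)
        X = X / np.where(sd > 0, sd, 1.0)

    pca = PCA(n_components=dims, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.T  # unit-norm columns

    # deterministic sign: strongest loading of each dimension positive
    signs = np.sign(loadings[np.abs(loadings).argmax(axis=0), range(dims)])
    signs[signs == 0] = 1.0
    loadings = loadings * signs
    scores = scores * signs

    contrib = loadings**2
    contrib = contrib / contrib.sum(axis=0)
    dims_idx = [f"dim{i + 1}" for i in range(dims)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=meta.index, columns=dims_idx),
        loadings=pd.DataFrame(loadings, index=table.values.index, columns=dims_idx),
        explained_frac=pca.explained_variance_ratio_.copy(),
        contributions=pd.DataFrame(
            contrib, index=table.values.index, columns=dims_idx
        ),
        samples=meta.copy(),
    )


def separating_dimension(pca: PcaResult, condition_key: str = "condition") -> str:
    """Dimension with the largest absolute difference of condition score
    means — the axis along which the two conditions separate."""
    groups = pca.samples[condition_key]
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise DataError(f"expected two conditions, got {list(levels)}")
    means = pca.scores.groupby(groups.loc[pca.scores.index]).mean()
    diff = (means.loc[levels[0]] - means.loc[levels[1]]).abs()
    return str(diff.idxmax())


def plot_scores(pca: PcaResult, path: str, condition_key: str = "condition"):
    """Scatter the first two dimensions, colored by condition."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for cond, sub in pca.samples.groupby(condition_key):
        pts = pca.scores.loc[sub.index]
        ax.scatter(pts.iloc[:, 0], pts.iloc[:, 1], label=str(cond), alpha=0.8)
    ax.set_xlabel(f"dim1 ({pca.explained_frac[0]:.1%})")
    ax.set_ylabel(f"dim2 ({pca.explained_frac[1]:.1%})")
    ax.legend(title=condition_key)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
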