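"""Bulk differential expression for the 2 x 2 age x genotype design.

Workflow per strain: filter low-count genes, log2-CPM normalize, residualize
technical covariates (library-prep batch, concentration) with the biological
design protected, fit per-gene OLS on the four group means, and test three
contrasts:

``age``
    mean(10M) - mean(4M), averaged over genotype.
``genotype``
    mean(TG) - mean(WT), averaged over age.
``age_x_genotype``
    either the transgenic-aged cell versus the mean of the other three cells
    (``vs_rest`` style: which transcripts move in aged TG animals relative to
    everything else) or the classical difference-in-differences
    (``classical`` style).

P-values are two-sided t-tests on the contrast; multiplicity is controlled
with Benjamini-Yekutieli, which remains valid under the arbitrary dependence
expected between overlapping contrasts.  Genes are ranked by the signed
log10 p metric ``sign(LFC) * (-log10 p)`` for downstream preranked
enrichment and cross-strain rank correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import (
    BulkExperiment,
    NormalizedMatrix,
    ParameterError,
    warn,
)

P_FLOOR = 1e-300

CONTRASTS = ("age", "genotype", "age_x_genotype")
# group-mean order used throughout: (WT_4M, WT_10M, TG_4M, TG_10M)
_CELL_ORDER = (("WT", "4M"), ("WT", "10M"), ("TG", "4M"), ("TG", "10M"))
_CONTRAST_VECTORS = {
    "age": np.array([-0.5, 0.5, -0.5, 0.5]),
    "genotype": np.array([-0.5, -0.5, 0.5, 0.5]),
    ("age_x_genotype", "vs_rest"): np.array([-1 / 3, -1 / 3, -1 / 3, 1.0]),
    ("age_x_genotype", "classical"): np.array([1.0, -1.0, -1.0, 1.0]),
}


@dataclass
class DEResult:
    """Per-gene effect sizes and p-values for one contrast."""

    contrast: str
    table: pd.DataFrame  # index gene; columns lfc, p, p_adj, metric

    def __post_init__(self) -> None:
        t = self.table
        if (t["p_adj"] + 1e-12 < t["p"]).any():
            raise ParameterError("p_adj must be >= p")


def filter_low_counts(
    experiment: BulkExperiment, min_mean: float = 5.0, min_samples: int = 10
) -> BulkExperiment:
    """Drop genes whose mean raw count does not exceed ``min_mean`` in at
    least ``min_samples`` samples (gene order preserved).

    The retention rule mirrors discarding transcripts with average raw counts
    <= ``min_mean`` outside a core of ``min_samples`` samples: a gene is kept
    when at least ``min_samples`` of its per-sample counts exceed
    ``min_mean``.
    """
    if min_mean < 0 or min_samples < 0:
        raise ParameterError("thresholds must be >= 0")
    counts = experiment.counts
    keep = (counts.to_numpy() > min_mean).sum(axis=1) >= min_samples
    if not keep.any():
        warn("filter_low_counts removed every gene")
    return BulkExperiment(counts.loc[keep], experiment.samples)


def normalize_log_cpm(
    experiment: BulkExperiment, pseudocount: float = 0.5
) -> NormalizedMatrix:
    """log2(1e6 * count / library_size + pseudocount) per gene and sample."""
    if pseudocount <= 0:
        raise ParameterError("pseudocount must be positive")
    lib = experiment.counts.sum(axis=0)
    zero = lib.index[lib == 0]
    if len(zero):
        raise ParameterError(f"zero library size for sample(s): {list(zero)}")
    values = np.log2(1e6 * experiment.counts / lib + pseudocount)
    return NormalizedMatrix(values=values, library_sizes=lib, pseudocount=pseudocount)


def _design_columns(samples: pd.DataFrame) -> pd.DataFrame:
    """Protected biological design: one indicator per (genotype, age) cell."""
    cols = {}
    for genotype, age in _CELL_ORDER:
        cols[f"cell_{genotype}_{age}"] = (
            (samples["genotype"] == genotype) & (samples["age"] == age)
        ).astype(float)
    return pd.DataFrame(cols, index=samples.index)


def _nuisance_columns(covariates: pd.DataFrame) -> pd.DataFrame:
    """Expand nuisance covariates: categoricals to centred dummies, scalars centred."""
    cols = {}
    for name in covariates.columns:
        col = covariates[name]
        if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=name, drop_first=True).astype(float)
            for c in dummies.columns:
                cols[c] = dummies[c] - dummies[c].mean()
        else:
            cols[name] = col.astype(float) - float(col.mean())
    out = pd.DataFrame(cols, index=covariates.index)
    # constant covariates carry no removable variation
    return out.loc[:, out.std(axis=0) > 0]


def residualize_covariates(
    matrix: NormalizedMatrix,
    covariates: pd.DataFrame,
    design: pd.DataFrame,
) -> NormalizedMatrix:
    """Remove the fitted nuisance component from a joint least-squares fit.

    The protected ``design`` (per-sample biological factors with columns
    ``genotype`` and ``age``, or an explicit design matrix) enters the fit so
    that nuisance estimates are not contaminated by biology; only the
    nuisance component is subtracted, leaving protected effects untouched.
    """
    if set(["genotype", "age"]).issubset(design.columns):
        d = _design_columns(design)
    else:
        d = design.astype(float)
    n = _nuisance_columns(covariates)
    if n.shape[1] == 0:
        return matrix
    x = np.hstack([d.to_numpy(), n.to_numpy()])
    names = list(d.columns) + list(n.columns)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # identify aliased columns via rank-revealing QR
        _, r, piv = _pivoted_qr(x)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(x.shape) * np.finfo(float).eps
        bad = [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
        bad += [names[p] for p in piv[len(diag):]]
        raise ParameterError(f"rank-deficient design; aliased columns: {bad}")
    y = matrix.values.to_numpy()  # genes x samples
    beta, *_ = np.linalg.lstsq(x, y.T, rcond=None)
    n_start = d.shape[1]
    fitted_nuisance = n.to_numpy() @ beta[n_start:, :]
    cleaned = matrix.values - fitted_nuisance.T
    return NormalizedMatrix(
        values=cleaned,
        library_sizes=matrix.library_sizes,
        pseudocount=matrix.pseudocount,
    )


def _pivoted_qr(x: np.ndarray):
    from scipy.linalg import qr

    return qr(x, mode="economic", pivoting=True)


def fit_two_by_two_model(
    matrix: NormalizedMatrix,
    samples: pd.DataFrame,
    contrast_style: str = "vs_rest",
) -> dict[str, DEResult]:
    """Per-gene OLS on the four (genotype, age) group means, three contrasts.

    One strain at a time.  Returns a DEResult per contrast with BY-adjusted
    p-values and the signed log10-p ranking metric already attached.
    """
    if contrast_style not in ("vs_rest", "classical"):
        raise ParameterError(f"unknown contrast_style {contrast_style!r}")
    x = _design_columns(samples).to_numpy()
    counts_per_cell = x.sum(axis=0)
    if (counts_per_cell == 0).any():
        empty = [
            f"{g}_{a}" for (g, a), c in zip(_CELL_ORDER, counts_per_cell) if c == 0
        ]
        raise ParameterError(f"empty design cell(s): {empty}")
    y = matrix.values.to_numpy()  # genes x samples
    n_samples = y.shape[1]
    df_resid = n_samples - 4
    if df_resid <= 0:
        raise ParameterError("not enough samples for residual degrees of freedom")

    # cell-mean parametrization: beta = group means, closed form
    means = (y @ x) / counts_per_cell  # genes x 4
    fitted = means @ x.T
    rss = ((y - fitted) ** 2).sum(axis=1)
    sigma2 = rss / df_resid

    out = {}
    for contrast in CONTRASTS:
        key = (contrast, contrast_style) if contrast == "age_x_genotype" else contrast
        c = _CONTRAST_VECTORS[key]
        est = means @ c
        var_scale = float((c**2 / counts_per_cell).sum())
        se = np.sqrt(sigma2 * var_scale)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, est / np.where(se > 0, se, 1.0), 0.0)
        p = 2.0 * stats.t.sf(np.abs(t), df_resid)
        p = np.clip(p, 0.0, 1.0)
        p_adj = adjust_by(p)
        tab = pd.DataFrame(
            {"lfc": est, "p": p, "p_adj": p_adj}, index=matrix.genes
        )
        tab["metric"] = _signed_log10(tab["lfc"].to_numpy(), tab["p"].to_numpy())
        out[contrast] = DEResult(contrast=contrast, table=tab)
    return out


def adjust_by(p) -> np.ndarray:
    """Benjamini-Yekutieli step-up adjusted p-values (arbitrary dependence)."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ParameterError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_by")[1]


def _signed_log10(lfc: np.ndarray, p: np.ndarray) -> np.ndarray:
    if (p <= 0).any():
        warn(f"{int((p <= 0).sum())} zero p-value(s) floored at {P_FLOOR}")
    p = np.maximum(p, P_FLOOR)
    return np.sign(lfc) * (-np.log10(p))


def signed_ranking(result: DEResult) -> pd.Series:
    """Genes ordered most-upregulated to most-downregulated by the metric."""
    metric = result.table["metric"]
    return metric.sort_values(ascending=False, kind="mergesort")


def pca_coordinates(matrix: NormalizedMatrix, n_components: int = 2) -> pd.DataFrame:
    """Per-sample principal-component scores (outlier-inspection hook)."""
    y = matrix.values.to_numpy()
    centered = (y - y.mean(axis=1, keepdims=True)).T  # samples x genes
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    k = min(n_components, s.size)
    return pd.DataFrame(
        u[:, :k] * s[:k],
        index=matrix.samples,
        columns=[f"PC{i+1}" for i in range(k)],
    )


def rank_correlation(
    result_a: DEResult,
    result_b: DEResult,
    alpha: float = 0.05,
) -> dict:
    """Spearman correlation of ranking metrics on genes significant in either.

    Returns rho, two-sided p, Fisher-z 95% CI and the subset size.
    """
    sig = (result_a.table["p_adj"] < alpha) | (result_b.table["p_adj"] < alpha)
    genes = result_a.table.index[sig.reindex(result_a.table.index, fill_value=False)]
    genes = genes.intersection(result_b.table.index)
    if len(genes) < 3:
        raise ParameterError(
            f"only {len(genes)} genes significant in either result (need >= 3)"
        )
    a = result_a.table.loc[genes, "metric"]
    b = result_b.table.loc[genes, "metric"]
    rho, p = stats.spearmanr(a, b)
    n = len(genes)
    if abs(rho) >= 1.0 or n <= 3:
        ci = (rho, rho)
    else:
        z = np.arctanh(rho)
        se = 1.0 / np.sqrt(n - 3)
        ci = (float(np.tanh(z - 1.959964 * se)), float(np.tanh(z + 1.959964 * se)))
    return {"rho": float(rho), "p": float(p), "ci": ci, "n": n}
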