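"""Single-microglia processing: QC, normalization, state scores and DE.

Cells are filtered on read depth (< 750 reads), mitochondrial fraction
(> 5%) and a doublet cap on total counts; genes detected in too few cells
are discarded afterwards.  Expression is library-size log-normalized
(``ln(1 + scale * umi / total)``).  Microglial states (homeostatic HM versus
activated ARM and friends) are assigned by signature module scores — mean
expression over a marker set minus the mean over expression-matched random
control genes — taking the argmax over state signatures.  ARM-vs-HM
differential expression uses a two-sided Wilcoxon rank-sum test with
Bonferroni correction; natural-log fold changes with a +1 stabilizer on
de-logged means follow the convention the |0.2| significance threshold
refers to.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse, stats

from .containers import ParameterError, warn

FAIL_REASONS = ("low_reads", "high_mito", "doublet_cap")


@dataclass
class CellQCReport:
    cells: pd.DataFrame  # index barcode; total_counts, mito_frac, passed, reason
    genes: pd.DataFrame  # index gene; n_cells_detected, retained

    @property
    def n_passed(self) -> int:
        return int(self.cells["passed"].sum())


def _dense(x) -> np.ndarray:
    return x.toarray() if sparse.issparse(x) else np.asarray(x)


def qc_filter(
    cells: ad.AnnData,
    min_reads: int = 750,
    max_mito: float = 0.05,
    doublet_cap: float = 30_000,
    min_cells_per_gene: int = 100,
) -> tuple[ad.AnnData, CellQCReport]:
    """Apply the read-depth / mitochondrial / doublet rules, then gene filter.

    Each failed cell records exactly one primary reason, checked in the
    order reads -> mito -> doublet.  The doublet cap applies to total
    counts.  Genes detected in fewer than ``min_cells_per_gene`` surviving
    cells are discarded.
    """
    if min_reads < 0 or max_mito < 0 or doublet_cap <= 0:
        raise ParameterError("QC thresholds must be positive")
    x = _dense(cells.X)
    total = (
        cells.obs["total_counts"].to_numpy()
        if "total_counts" in cells.obs
        else x.sum(axis=1)
    )
    if "mito_frac" in cells.obs:
        mito = cells.obs["mito_frac"].to_numpy()
    elif "mito" in cells.var:
        mito = x[:, cells.var["mito"].to_numpy()].sum(axis=1) / np.maximum(total, 1)
    else:
        mito = np.zeros(cells.n_obs)

    reason = np.array([""] * cells.n_obs, dtype=object)
    reason[(reason == "") & (total < min_reads)] = "low_reads"
    reason[(reason == "") & (mito > max_mito)] = "high_mito"
    reason[(reason == "") & (total > doublet_cap)] = "doublet_cap"
    passed = reason == ""

    cell_report = pd.DataFrame(
        {
            "total_counts": total,
            "mito_frac": mito,
            "passed": passed,
            "reason": reason,
        },
        index=cells.obs_names,
    )
    if not passed.any():
        raise ParameterError("no cells survive QC")

    kept = cells[passed].copy()
    detected = (_dense(kept.X) > 0).sum(axis=0)
    retained = detected >= min_cells_per_gene
    gene_report = pd.DataFrame(
        {"n_cells_detected": detected, "retained": retained},
        index=cells.var_names,
    )
    kept = kept[:, retained].copy()
    return kept, CellQCReport(cells=cell_report, genes=gene_report)


def normalize_cells(cells: ad.AnnData, scale: float = 1e4) -> ad.AnnData:
    """ln(1 + scale * umi / cell_total); scale-invariant per cell."""
    x = _dense(cells.X).astype(float)
    total = x.sum(axis=1)
    if (total <= 0).any():
        raise ParameterError("zero-total cell encountered after QC")
    out = cells.copy()
    out.X = np.log1p(scale * x / total[:, None])
    return out


def module_score(
    normalized: ad.AnnData,
    marker_set,
    n_bins: int = 24,
    n_ctrl_per_gene: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Per-cell signature score against expression-matched random controls.

    Genes are binned by mean expression (``n_bins`` equal-count bins);
    for each marker gene, ``n_ctrl_per_gene`` control genes are drawn from
    its bin (marker genes themselves excluded).  The score is the mean
    marker expression minus the mean over the pooled control draws.
    """
    x = _dense(normalized.X)
    genes = normalized.var_names
    members = genes.isin(set(marker_set))
    if not members.any():
        raise ParameterError("marker set does not intersect the genes")
    rng = np.random.default_rng(seed)
    mean_expr = x.mean(axis=0)
    order = np.argsort(mean_expr, kind="mergesort")
    bins = np.empty(len(genes), dtype=int)
    bins[order] = np.arange(len(genes)) * n_bins // len(genes)

    member_idx = np.where(members)[0]
    ctrl_draws = []
    for gi in member_idx:
        pool = np.where((bins == bins[gi]) & ~members)[0]
        b = bins[gi]
        while pool.size == 0:
            b = max(b - 1, 0) if b > 0 else b + 1
            warn("empty control bin; falling back to nearest bin")
            pool = np.where((bins == b) & ~members)[0]
            if b == 0 or b == n_bins - 1:
                break
        if pool.size == 0:
            raise ParameterError("no control genes available outside the set")
        ctrl_draws.append(rng.choice(pool, size=n_ctrl_per_gene, replace=True))
    ctrl = np.concatenate(ctrl_draws)
    score = x[:, member_idx].mean(axis=1) - x[:, ctrl].mean(axis=1)
    return pd.Series(score, index=normalized.obs_names, name="score")


@dataclass
class StateAssignment:
    scores: pd.DataFrame  # cell x state
    states: pd.Series  # cell -> state label
    fractions: pd.DataFrame  # group x state


def assign_states(
    scores: pd.DataFrame,
    groups: pd.Series,
    homeostatic: str = "HM",
) -> StateAssignment:
    """Argmax state per cell (lexicographic tie-break), plus group fractions."""
    if scores.shape[1] < 2:
        raise ParameterError("need at least 2 state signatures")
    if homeostatic not in scores.columns:
        raise ParameterError(f"missing homeostatic signature {homeostatic!r}")
    cols = sorted(scores.columns)  # lexicographic order makes idxmax ties stable
    states = scores[cols].idxmax(axis=1)
    frac = (
        pd.crosstab(groups, states, normalize="index")
        .reindex(columns=cols, fill_value=0.0)
    )
    return StateAssignment(scores=scores, states=states, fractions=frac)


def state_de(
    normalized: ad.AnnData,
    group_a_cells,
    group_b_cells,
    lfc_threshold: float = 0.2,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Wilcoxon rank-sum DE between two cell populations (A vs B).

    LFC is ``ln((mean(expm1(A)) + 1) / (mean(expm1(B)) + 1))``; significance
    requires |lfc| strictly above the threshold and Bonferroni-adjusted
    p < alpha.
    """
    a_idx = normalized.obs_names.get_indexer(pd.Index(group_a_cells))
    b_idx = normalized.obs_names.get_indexer(pd.Index(group_b_cells))
    if (a_idx < 0).any() or (b_idx < 0).any():
        raise ParameterError("unknown cell barcodes")
    if len(a_idx) < 3 or len(b_idx) < 3:
        raise ParameterError("need at least 3 cells per side")
    x = _dense(normalized.X)
    xa, xb = x[a_idx], x[b_idx]

    expressed = (xa.sum(axis=0) > 0) | (xb.sum(axis=0) > 0)
    if (~expressed).any():
        warn(f"skipping {int((~expressed).sum())} gene(s) expressed in neither group")

    mean_a = np.expm1(xa).mean(axis=0)
    mean_b = np.expm1(xb).mean(axis=0)
    lfc = np.log((mean_a + 1.0) / (mean_b + 1.0))

    p = np.ones(x.shape[1])
    cols = np.where(expressed)[0]
    res = stats.mannwhitneyu(
        xa[:, cols], xb[:, cols], alternative="two-sided", axis=0, method="auto"
    )
    p[cols] = res.pvalue
    p_adj = np.minimum(p * expressed.sum(), 1.0)
    out = pd.DataFrame(
        {
            "lfc": lfc,
            "p": p,
            "p_adj": p_adj,
            "tested": expressed,
        },
        index=normalized.var_names,
    )
    out["significant"] = (np.abs(out["lfc"]) > lfc_threshold) & (out["p_adj"] < alpha)
    out.loc[~out["tested"], "significant"] = False
    return out


def state_de_concordance(result_a: pd.DataFrame, result_b: pd.DataFrame) -> dict:
    """Spearman correlation of LFCs over genes significant in either result."""
    shared = result_a.index.intersection(result_b.index)
    sig = (
        result_a.loc[shared, "significant"] | result_b.loc[shared, "significant"]
    )
    genes = shared[sig]
    if len(genes) < 3:
        raise ParameterError(f"only {len(genes)} shared significant genes (need >= 3)")
    rho, p = stats.spearmanr(
        result_a.loc[genes, "lfc"], result_b.loc[genes, "lfc"]
    )
    return {"rho": float(rho), "p": float(p), "n": int(len(genes))}
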