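"""Unsigned co-expression networks: soft power, TOM, modules, eigengenes.

The network is built from the absolute Pearson correlation raised to a soft
power beta, chosen as the smallest candidate whose connectivity distribution
satisfies an approximate scale-free topology fit (signed R^2 >= target).
Topological overlap quantifies shared neighborhood:

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),   l_ij = sum_u a_iu a_uj

with the convention a_ii = 0 for connectivity and TOM_ii = 1.  Modules come
from average-linkage hierarchical clustering of 1 - TOM with a static height
cut, a minimum-size filter and eigengene-correlation merging — a deliberately
simple stand-in for dynamic tree cutting whose output feeds the same
downstream enrichment logic.  Each module is summarized by its eigengene,
the first principal component across samples of the gene-standardized
submatrix, oriented to correlate positively with the module mean profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .containers import NormalizedMatrix, ParameterError, warn

UNASSIGNED = "unassigned"


@dataclass
class NetworkConfig:
    beta: int = 3
    r2_target: float = 0.9
    min_module_size: int = 30
    merge_corr: float = 0.75
    cut_height: float = 0.95

    def __post_init__(self) -> None:
        if self.beta < 1:
            raise ParameterError("beta must be >= 1")
        if not 0 < self.r2_target <= 1:
            raise ParameterError("r2_target must be in (0, 1]")


@dataclass
class ModulePartition:
    labels: pd.Series  # gene -> module name
    eigengenes: pd.DataFrame = field(default_factory=pd.DataFrame)  # module x sample
    tom: pd.DataFrame | None = None

    def module_genes(self, name: str) -> list[str]:
        return sorted(self.labels.index[self.labels == name])

    @property
    def modules(self) -> list[str]:
        return [m for m in self.labels.unique() if m != UNASSIGNED]


def _drop_constant(values: pd.DataFrame) -> pd.DataFrame:
    sd = values.std(axis=1, ddof=1)
    constant = sd.index[sd == 0]
    if len(constant):
        warn(f"excluding {len(constant)} zero-variance gene(s)")
        values = values.drop(index=constant)
    return values


def _adjacency(values: np.ndarray, beta: int) -> np.ndarray:
    corr = np.corrcoef(values)
    bad = np.abs(corr) > 1 + 1e-12
    if bad.any():
        raise ParameterError("numerical correlation outside [-1, 1]")
    a = np.abs(np.clip(corr, -1.0, 1.0)) ** beta
    np.fill_diagonal(a, 0.0)
    return a


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the log-log degree-density fit on equal-count bins."""
    k = k[k > 0]
    if k.size < n_bins:
        n_bins = max(2, k.size // 2)
    qs = np.quantile(k, np.linspace(0, 1, n_bins + 1))
    qs = np.unique(qs)
    if qs.size < 3:
        return 0.0
    counts, edges = np.histogram(k, bins=qs)
    widths = np.diff(edges)
    dens = counts / (counts.sum() * widths)
    mids = np.array(
        [k[(k >= lo) & (k <= hi)].mean() for lo, hi in zip(edges[:-1], edges[1:])]
    )
    ok = (dens > 0) & (mids > 0)
    if ok.sum() < 3:
        return 0.0
    x, y = np.log10(mids[ok]), np.log10(dens[ok])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float((resid**2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(r2 * -np.sign(slope))


def pick_soft_power(
    matrix: NormalizedMatrix,
    candidate_powers=(1, 2, 3, 4, 5, 6, 7, 8, 10, 12),
    r2_target: float = 0.9,
) -> tuple[int, pd.DataFrame]:
    """Smallest candidate power with signed scale-free R^2 >= target.

    Falls back (with a warning) to the best-fitting power when no candidate
    reaches the target.  Returns the per-power fit table as well.
    """
    values = _drop_constant(matrix.values)
    if values.shape[1] < 8:
        raise ParameterError("need at least 8 samples for a stable correlation")
    powers = list(candidate_powers)
    if powers != sorted(powers):
        raise ParameterError("candidate powers must be ascending")
    corr_abs = np.abs(np.corrcoef(values.to_numpy()))
    np.fill_diagonal(corr_abs, 0.0)
    rows = []
    for beta in powers:
        a = corr_abs**beta
        k = a.sum(axis=1)
        rows.append(
            {"power": beta, "signed_r2": _scale_free_fit(k), "mean_k": float(k.mean())}
        )
    fit_table = pd.DataFrame(rows).set_index("power")
    ok = fit_table.index[fit_table["signed_r2"] >= r2_target]
    if len(ok):
        beta = int(ok[0])
    else:
        beta = int(fit_table["signed_r2"].idxmax())
        warn(
            f"no candidate power reaches signed R^2 {r2_target}; "
            f"using best fit beta={beta}"
        )
    return beta, fit_table


def adjacency_and_tom(matrix: NormalizedMatrix, beta: int) -> pd.DataFrame:
    """Topological overlap matrix (genes x genes, symmetric, diag 1)."""
    values = _drop_constant(matrix.values)
    a = _adjacency(values.to_numpy(), beta)
    k = a.sum(axis=1)
    l = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (l + a) / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(tom, index=values.index, columns=values.index)


def module_eigengene(matrix: NormalizedMatrix, module_genes) -> pd.Series:
    """First principal component of the gene-standardized module submatrix.

    Oriented so the eigengene correlates positively with the module's mean
    expression profile; exact orientation ties break toward a positive
    loading on the lexicographically first module gene.
    """
    genes = sorted(set(module_genes) & set(matrix.genes))
    if len(genes) < 2:
        raise ParameterError("module needs at least 2 genes present")
    sub = matrix.values.loc[genes]
    if sub.shape[1] < 2:
        raise ParameterError("need at least 2 samples")
    z = sub.sub(sub.mean(axis=1), axis=0)
    sd = sub.std(axis=1, ddof=1).replace(0.0, 1.0)
    z = z.div(sd, axis=0)
    u, s, vt = np.linalg.svd(z.to_numpy(), full_matrices=False)
    pc1 = vt[0]  # per-sample scores (unit norm)
    mean_profile = z.to_numpy().mean(axis=0)
    orient = float(np.dot(pc1, mean_profile))
    if abs(orient) < 1e-12:
        orient = float(u[0, 0])  # loading of first (sorted) gene
    if orient < 0:
        pc1 = -pc1
    return pd.Series(pc1, index=matrix.samples, name="eigengene")


def detect_modules(
    tom: pd.DataFrame,
    config: NetworkConfig,
    matrix: NormalizedMatrix | None = None,
) -> ModulePartition:
    """Cluster 1 - TOM, cut, size-filter and eigengene-merge into modules.

    The cut is a static absolute height on the 1 - TOM dendrogram scale
    (default 0.95): co-expressed subtrees complete well below it while
    merges between unrelated genes sit near 1.  Labels are ``M1, M2, ...``
    ordered by decreasing size; genes in clusters below ``min_module_size``
    get the reserved label ``unassigned``.  When the expression matrix is
    provided, modules whose eigengenes correlate (absolutely) above
    ``merge_corr`` are merged iteratively and eigengenes are returned.
    """
    genes = tom.index
    diss = 1.0 - tom.to_numpy()
    np.fill_diagonal(diss, 0.0)
    condensed = squareform(diss, checks=False)
    link = hierarchy.linkage(condensed, method="average")
    raw = hierarchy.fcluster(link, t=config.cut_height, criterion="distance")

    labels = pd.Series(UNASSIGNED, index=genes, dtype=object)
    sizes = pd.Series(raw).value_counts()
    keep = [c for c in sizes.index if sizes[c] >= config.min_module_size]
    groups = {c: genes[raw == c] for c in keep}

    if matrix is not None and len(groups) > 1:
        groups = _merge_by_eigengene(groups, matrix, config.merge_corr)

    ordered = sorted(groups.values(), key=lambda g: (-len(g), tuple(sorted(g))))
    eigengenes = {}
    for i, members in enumerate(ordered, start=1):
        name = f"M{i}"
        labels.loc[members] = name
        if matrix is not None and len(members) >= 2:
            eigengenes[name] = module_eigengene(matrix, members)
    if not ordered:
        warn("no module reaches min_module_size; empty partition")
    eg = pd.DataFrame(eigengenes).T if eigengenes else pd.DataFrame()
    return ModulePartition(labels=labels, eigengenes=eg, tom=tom)


def _merge_by_eigengene(groups: dict, matrix: NormalizedMatrix, merge_corr: float):
    groups = {k: pd.Index(v) for k, v in groups.items()}
    while len(groups) > 1:
        keys = sorted(groups, key=lambda k: tuple(sorted(groups[k]))[0] if len(groups[k]) else "")
        egs = {k: module_eigengene(matrix, groups[k]) for k in keys}
        best, best_val = None, -1.0
        for i, ki in enumerate(keys):
            for kj in keys[i + 1:]:
                c = abs(float(np.corrcoef(egs[ki], egs[kj])[0, 1]))
                if c > best_val:
                    best_val, best = c, (ki, kj)
        if best is None or best_val <= merge_corr:
            break
        ki, kj = best
        groups[ki] = groups[ki].union(groups[kj])
        del groups[kj]
    return groups
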