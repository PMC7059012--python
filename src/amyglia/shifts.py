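"""Baseline-anchored z-score statistic for cell-type composition shifts.

Per gene i and sample s, expression is z-normalized against the young
wild-type baseline group:

    Z_is = (E_is - mean(E_i over baseline samples)) / sd(E_i over all samples)

The composition statistic for a cell-type marker set t in an experimental
group g is the plain mean ``Z_tg`` of Z_is over set genes and group samples.
Significance comes from an empirical null: many random gene sets of the same
size yield a population of ``Z_rtg`` values whose Gaussian fit supplies a
CDF-based p-value, Bonferroni-corrected over (non-baseline groups x sets).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import NormalizedMatrix, ParameterError, warn


@dataclass
class ShiftResult:
    set_name: str
    group: str
    z_tg: float
    null_mean: float
    null_sd: float
    p_empirical: float
    p_bonf: float
    null_normal: bool  # D'Agostino normality of the resampled null at alpha=0.01


def znorm_to_baseline(
    matrix: NormalizedMatrix, baseline_samples
) -> pd.DataFrame:
    """Z_is with the baseline-group mean as center and the all-sample sd as scale."""
    baseline = pd.Index(baseline_samples)
    if len(baseline) < 2:
        raise ParameterError("baseline needs at least 2 samples")
    missing = baseline.difference(matrix.samples)
    if len(missing):
        raise ParameterError(f"baseline samples absent from matrix: {list(missing)}")
    values = matrix.values
    sd = values.std(axis=1, ddof=1)
    constant = sd.index[sd == 0]
    if len(constant):
        warn(f"excluding {len(constant)} constant gene(s) from z-normalization")
        values = values.drop(index=constant)
        sd = sd.drop(index=constant)
    center = values[baseline].mean(axis=1)
    return values.sub(center, axis=0).div(sd, axis=0)


def group_set_score(
    z_matrix: pd.DataFrame, gene_set, group_samples
) -> float:
    """Mean of Z_is over set genes x group samples (the Z_tg statistic)."""
    genes = z_matrix.index.intersection(pd.Index(sorted(set(gene_set))))
    if len(genes) == 0:
        raise ParameterError("gene set does not intersect the z-matrix")
    cols = pd.Index(group_samples)
    return float(z_matrix.loc[genes, cols].to_numpy().mean())


def shift_test(
    z_matrix: pd.DataFrame,
    gene_sets: dict,
    groups: pd.Series,
    baseline_group: str,
    n_random: int = 10_000,
    seed: int = 0,
    sidedness: str = "two-sided",
    n_tests: int | None = None,
) -> pd.DataFrame:
    """Empirical shift test for every (gene set, non-baseline group) pair.

    ``groups`` maps sample -> group label.  Random same-size gene sets are
    drawn without replacement from the full z-matrix universe; the same
    draws are reused across groups for a given set size.  ``n_tests`` for
    the Bonferroni correction defaults to (#non-baseline groups) x (#sets).
    """
    if n_random < 1000:
        raise ParameterError("n_random must be >= 1000")
    if sidedness not in ("two-sided", "greater", "less"):
        raise ParameterError(f"unknown sidedness {sidedness!r}")
    max_size = max(len(set(s) & set(z_matrix.index)) for s in gene_sets.values())
    if len(z_matrix.index) < 2 * max_size:
        raise ParameterError("gene universe must be >= 2x the largest set")
    rng = np.random.default_rng(seed)
    test_groups = [g for g in pd.unique(groups) if g != baseline_group]
    if n_tests is None:
        n_tests = len(test_groups) * len(gene_sets)

    # per-gene group means once; null Z_rtg is then a gene subset average
    gm = pd.DataFrame(
        {g: z_matrix[groups.index[groups == g]].mean(axis=1) for g in test_groups}
    )
    gm_np = gm.to_numpy()
    n_genes = gm_np.shape[0]

    draws_cache: dict[int, np.ndarray] = {}
    rows = []
    for name, gene_set in sorted(gene_sets.items()):
        genes = z_matrix.index.intersection(pd.Index(sorted(set(gene_set))))
        k = len(genes)
        if k == 0:
            raise ParameterError(f"set {name!r} does not intersect the z-matrix")
        if k not in draws_cache:
            idx = np.argsort(rng.random((n_random, n_genes)), axis=1)[:, :k]
            draws_cache[k] = idx
        null = gm_np[draws_cache[k]].mean(axis=1)  # n_random x groups
        mu = null.mean(axis=0)
        sd = null.std(axis=0, ddof=1)
        if (sd == 0).any():
            raise ParameterError("degenerate null (zero spread)")
        normal_ok = [
            bool(stats.normaltest(null[:, j]).pvalue > 0.01)
            for j in range(null.shape[1])
        ]
        for j, g in enumerate(test_groups):
            z_tg = group_set_score(z_matrix, genes, groups.index[groups == g])
            zz = (z_tg - mu[j]) / sd[j]
            if sidedness == "two-sided":
                p = 2.0 * stats.norm.sf(abs(zz))
            elif sidedness == "greater":
                p = stats.norm.sf(zz)
            else:
                p = stats.norm.cdf(zz)
            p = float(min(p, 1.0))
            rows.append(
                ShiftResult(
                    set_name=name,
                    group=g,
                    z_tg=z_tg,
                    null_mean=float(mu[j]),
                    null_sd=float(sd[j]),
                    p_empirical=p,
                    p_bonf=float(min(1.0, p * n_tests)),
                    null_normal=normal_ok[j],
                )
            )
    return pd.DataFrame([r.__dict__ for r in rows])
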