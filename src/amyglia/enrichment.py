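"""Preranked gene-set enrichment and discrete-overlap tests.

Nested GWAS risk-gene sets are thresholds on a per-gene association p-value
(``P_mar``); their enrichment in a ranked differential-expression list is
measured with the weighted Kolmogorov-Smirnov running-sum statistic
(enrichment score, ES) and a gene-set resampling null.  Overlap of discrete
sets (e.g. cell-type markers versus a co-expression module) uses a one-sided
hypergeometric test with a log2 odds ratio.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .bulk_de import adjust_by
from .containers import ParameterError, warn


def build_gwas_sets(
    table: pd.DataFrame,
    cutoffs,
    universe,
    orthology: dict | None = None,
) -> dict[str, list[str]]:
    """Nested risk-gene sets ``{g in universe : P_mar(g) < cutoff}``.

    ``table`` has columns ``gene`` and ``P_mar``; duplicates (e.g. after
    orthology mapping) resolve to the minimum ``P_mar``.
    """
    universe = pd.Index(universe)
    if len(universe) == 0:
        raise ParameterError("empty gene universe")
    cutoffs = list(cutoffs)
    if cutoffs != sorted(cutoffs):
        raise ParameterError("cutoffs must be sorted ascending")
    t = table.copy()
    if orthology:
        t["gene"] = t["gene"].map(lambda g: orthology.get(g, g))
    p = t.groupby("gene")["P_mar"].min()
    if ((p <= 0) | (p > 1)).any():
        raise ParameterError("P_mar must lie in (0, 1]")
    p = p[p.index.isin(universe)]
    return {
        f"P_mar<{c:g}": sorted(p.index[p < c]) for c in cutoffs
    }


def enrichment_score(
    ranked: pd.Series, gene_set, weight_exponent: float = 1.0
) -> tuple[float, np.ndarray]:
    """Weighted KS enrichment score with the full running sum.

    ``ranked`` maps gene -> metric, ordered most-up to most-down.  Hits
    increment by |metric|^p normalized over set members; misses by
    1/(N - N_hits).  The ES is the running-sum value of maximal absolute
    deviation from zero (signed).  Set genes absent from the ranking are
    dropped beforehand.
    """
    genes = ranked.index
    in_set = genes.isin(set(gene_set)).astype(bool)
    n_hit = int(in_set.sum())
    n = len(genes)
    if n_hit == 0:
        raise ParameterError("gene set does not intersect the ranking")
    if n_hit == n:
        raise ParameterError("gene set covers the entire ranking (miss denominator zero)")
    w = np.abs(ranked.to_numpy()) ** weight_exponent
    w = np.where(in_set, w, 0.0)
    total = w.sum()
    if total == 0:
        warn("all-zero hit weights; falling back to uniform increments")
        w = in_set.astype(float)
        total = w.sum()
    hit_step = w / total
    miss_step = (~in_set) / (n - n_hit)
    running = np.cumsum(hit_step - miss_step)
    es = float(running[np.argmax(np.abs(running))])
    return es, running


def _null_es(
    metric: np.ndarray,
    set_size: int,
    n_resamples: int,
    weight_exponent: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized ES for random same-size sets (positions-based computation)."""
    n = metric.size
    k = set_size
    w_all = np.abs(metric) ** weight_exponent
    # random k-subsets of positions, sorted row-wise
    pos = np.argsort(rng.random((n_resamples, n)), axis=1)[:, :k]
    pos.sort(axis=1)
    w = w_all[pos]
    tot = w.sum(axis=1, keepdims=True)
    degenerate = tot[:, 0] == 0
    if degenerate.any():
        w[degenerate] = 1.0
        tot = w.sum(axis=1, keepdims=True)
    cum_hit = np.cumsum(w, axis=1) / tot
    ranks = np.arange(k)
    miss = (pos - ranks) / (n - k)  # misses accumulated before each hit
    after = cum_hit - miss
    before = after - w / tot
    cand = np.concatenate([after, before], axis=1)
    idx = np.argmax(np.abs(cand), axis=1)
    return cand[np.arange(n_resamples), idx]


def preranked_test(
    ranked: pd.Series,
    gene_sets: dict,
    n_resamples: int = 1000,
    seed: int = 0,
    weight_exponent: float = 1.0,
) -> pd.DataFrame:
    """Gene-set resampling null for the preranked enrichment score.

    The null ES distribution comes from random same-size gene sets drawn
    from the ranked universe; p is the add-one tail among same-sign nulls,
    ``p = (1 + #{|ES_null| >= |ES|, same sign}) / (1 + #same sign)``, and the
    normalized score is ``NES = ES / mean(|ES_null| of the same sign)``.
    BY adjustment is computed across the sets in this call; when several
    contrasts are tested, concatenate raw p's and re-adjust jointly.
    """
    if n_resamples < 100:
        raise ParameterError("n_resamples must be >= 100")
    rng = np.random.default_rng(seed)
    metric = ranked.to_numpy()
    rows = []
    null_cache: dict[int, np.ndarray] = {}
    for name, gene_set in gene_sets.items():
        members = [g for g in gene_set if g in ranked.index]
        es, _ = enrichment_score(ranked, members, weight_exponent)
        k = len(set(members))
        if k not in null_cache:
            null_cache[k] = _null_es(metric, k, n_resamples, weight_exponent, rng)
        null = null_cache[k]
        same = null >= 0 if es >= 0 else null < 0
        n_same = int(same.sum())
        if n_same == 0:
            warn(f"no same-sign null draws for set {name!r}; p floored at 1")
            p = 1.0
            nes = np.nan
        else:
            p = (1 + int((np.abs(null[same]) >= abs(es)).sum())) / (1 + n_same)
            denom = float(np.abs(null[same]).mean())
            nes = es / denom if denom > 0 else np.nan
        rows.append({"set": name, "size": k, "es": es, "nes": nes, "p": p})
    out = pd.DataFrame(rows).set_index("set")
    out["p_adj"] = adjust_by(out["p"].to_numpy())
    return out


def fisher_set_enrichment(set_a, set_b, universe) -> dict:
    """One-sided overlap test of two sets against a common background.

    Returns the upper hypergeometric tail p for the observed overlap and a
    log2 odds ratio with Haldane 0.5 continuity applied only when a cell of
    the 2x2 table is zero.
    """
    universe = set(universe)
    if not universe:
        raise ParameterError("empty gene universe")
    sa = set(set_a) & universe
    sb = set(set_b) & universe
    if (set(set_a) - universe) or (set(set_b) - universe):
        warn("set members outside the universe were ignored")
    n = len(universe)
    a = len(sa & sb)
    b = len(sa - sb)
    c = len(sb - sa)
    d = n - a - b - c
    p = float(stats.hypergeom.sf(a - 1, n, len(sa), len(sb)))
    h = 0.5 if min(a, b, c, d) == 0 else 0.0
    lor = float(np.log2(((a + h) * (d + h)) / ((b + h) * (c + h))))
    return {"lor": lor, "p": p, "table": (a, b, c, d)}


def fisher_enrichment_table(
    modules: dict, gene_sets: dict, universe
) -> pd.DataFrame:
    """All (module x gene-set) overlap tests with joint BY adjustment."""
    rows = []
    for mod, mod_genes in modules.items():
        for name, gs in gene_sets.items():
            res = fisher_set_enrichment(mod_genes, gs, universe)
            rows.append(
                {
                    "module": mod,
                    "set": name,
                    "overlap": res["table"][0],
                    "lor": res["lor"],
                    "p": res["p"],
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = adjust_by(out["p"].to_numpy())
    return out
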