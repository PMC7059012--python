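"""Single-microglia units: QC rules, normalization closed forms, module
scores, state assignment and Wilcoxon DE against exact enumeration."""

import itertools

import anndata as ad
import numpy as np
import pandas as pd
import pytest

from amyglia import single_cell
from amyglia.containers import ParameterError


def adata_from_counts(counts, groups=None, mito_idx=()):
    counts = np.asarray(counts)
    n, g = counts.shape
    obs = pd.DataFrame(index=pd.Index([f"c{i}" for i in range(n)], name="barcode"))
    if groups is not None:
        obs["group"] = groups
    var = pd.DataFrame(
        {"mito": np.isin(np.arange(g), mito_idx)},
        index=pd.Index([f"g{j}" for j in range(g)], name="gene"),
    )
    return ad.AnnData(X=counts.astype(np.int64), obs=obs, var=var)


class TestQcFilter:
    def test_rule_by_rule_fixture(self):
        # (total, mito): (500,.01) low reads; (800,.06) high mito;
        # (40000,.01) doublet; (900,.01) survives
        n_genes = 10
        rows = []
        for total, mito in [(500, 0.01), (800, 0.06), (40000, 0.01), (900, 0.01)]:
            mito_counts = int(round(total * mito))
            row = np.zeros(n_genes, dtype=int)
            row[0] = mito_counts
            row[1:] = (total - mito_counts) // (n_genes - 1)
            row[-1] += total - row.sum()
            rows.append(row)
        adata = adata_from_counts(rows, mito_idx=[0])
        kept, report = single_cell.qc_filter(adata, min_cells_per_gene=0)
        assert report.cells["passed"].tolist() == [False, False, False, True]
        assert report.cells["reason"].tolist() == [
            "low_reads",
            "high_mito",
            "doublet_cap",
            "",
        ]
        assert kept.n_obs == 1

    def test_zero_gene_threshold_keeps_all_genes(self):
        adata = adata_from_counts(np.full((3, 5), 400), mito_idx=[])
        kept, _ = single_cell.qc_filter(
            adata, min_reads=0, max_mito=1.0, doublet_cap=1e12,
            min_cells_per_gene=0,
        )
        assert kept.shape == adata.shape

    def test_order_independence(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 300, size=(30, 20))
        adata = adata_from_counts(counts, mito_idx=[0])
        perm = rng.permutation(30)
        kept1, r1 = single_cell.qc_filter(adata, min_reads=2000,
                                          min_cells_per_gene=0)
        kept2, r2 = single_cell.qc_filter(adata[perm].copy(), min_reads=2000,
                                          min_cells_per_gene=0)
        assert set(kept1.obs_names) == set(kept2.obs_names)
        assert r1.cells.loc[kept2.obs_names, "passed"].all() == r2.cells[
            r2.cells["passed"]
        ]["passed"].all()

    def test_no_survivors_raises(self):
        adata = adata_from_counts(np.full((2, 4), 1), mito_idx=[])
        with pytest.raises(ParameterError):
            single_cell.qc_filter(adata)


class TestNormalizeCells:
    def test_closed_forms(self):
        counts = np.zeros((1, 3), dtype=int)
        counts[0] = [100, 9900, 0]
        norm = single_cell.normalize_cells(adata_from_counts(counts), scale=1e4)
        x = np.asarray(norm.X)
        assert x[0, 0] == pytest.approx(np.log(101))
        assert x[0, 0] == pytest.approx(4.6151, abs=1e-4)
        assert x[0, 2] == 0.0

    def test_depth_invariance(self):
        counts = np.array([[5, 10, 85]])
        n1 = single_cell.normalize_cells(adata_from_counts(counts))
        n2 = single_cell.normalize_cells(adata_from_counts(counts * 3))
        assert np.allclose(np.asarray(n1.X), np.asarray(n2.X))


class TestModuleScore:
    def test_constant_difference(self):
        # marker genes at 2.0, everything else at 0.5
        x = np.full((5, 40), 0.5)
        x[:, :4] = 2.0
        adata = adata_from_counts(np.ones((5, 40)))
        adata.X = x
        score = single_cell.module_score(
            adata, [f"g{j}" for j in range(4)], n_bins=1, seed=0
        )
        assert np.allclose(score, 1.5)

    def test_self_control_scores_near_zero(self):
        rng = np.random.default_rng(1)
        x = rng.normal(2.0, 0.1, size=(50, 1000))
        adata = adata_from_counts(np.ones((50, 1000)))
        adata.X = x
        score = single_cell.module_score(
            adata, [f"g{j}" for j in range(0, 1000, 10)], n_bins=1, seed=3
        )
        assert np.abs(score).max() < 0.05

    def test_seed_determinism(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(20, 200))
        adata = adata_from_counts(np.ones((20, 200)))
        adata.X = x
        s1 = single_cell.module_score(adata, [f"g{j}" for j in range(5)], seed=9)
        s2 = single_cell.module_score(adata, [f"g{j}" for j in range(5)], seed=9)
        assert s1.equals(s2)


class TestAssignStates:
    def test_argmax_and_tie_break(self):
        scores = pd.DataFrame(
            {"HM": [0.9, 0.5], "ARM": [0.1, 0.5]}, index=["c0", "c1"]
        )
        groups = pd.Series(["g", "g"], index=scores.index)
        out = single_cell.assign_states(scores, groups)
        assert out.states.loc["c0"] == "HM"
        assert out.states.loc["c1"] == "ARM"  # lexicographic tie-break

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(0)
        scores = pd.DataFrame(
            rng.normal(size=(100, 2)),
            columns=["ARM", "HM"],
            index=[f"c{i}" for i in range(100)],
        )
        groups = pd.Series(["a"] * 50 + ["b"] * 50, index=scores.index)
        out = single_cell.assign_states(scores, groups)
        assert np.allclose(out.fractions.sum(axis=1), 1.0, atol=1e-12)

    def test_missing_homeostatic_raises(self):
        scores = pd.DataFrame({"ARM": [1.0], "IRM": [0.5]}, index=["c0"])
        with pytest.raises(ParameterError):
            single_cell.assign_states(
                scores, pd.Series(["g"], index=["c0"])
            )


def exact_ranksum_p(a, b):
    """Two-sided exact Wilcoxon rank-sum by full enumeration."""
    pooled = np.concatenate([a, b])
    ranks = pd.Series(pooled).rank().to_numpy()
    obs = ranks[: len(a)].sum()
    n = len(pooled)
    stats_all = [
        ranks[list(c)].sum() for c in itertools.combinations(range(n), len(a))
    ]
    stats_all = np.array(stats_all)
    mu = stats_all.mean()
    more_extreme = np.abs(stats_all - mu) >= abs(obs - mu) - 1e-12
    return more_extreme.mean()


class TestStateDe:
    def _norm_adata(self, xa, xb):
        x = np.vstack([xa, xb])
        adata = adata_from_counts(np.ones_like(x, dtype=int))
        adata.X = x.astype(float)
        return adata

    def test_identical_groups_nothing_significant(self):
        x = np.tile(np.linspace(0.1, 1, 6), (8, 1))
        adata = self._norm_adata(x[:4], x[4:])
        out = single_cell.state_de(
            adata, adata.obs_names[:4], adata.obs_names[4:]
        )
        assert (out["p"] == 1.0).all()
        assert not out["significant"].any()

    def test_complete_separation_exact_p(self):
        # nA = nB = 4, no overlap: two-sided exact p = 2 / C(8,4) = 2/70
        xa = np.tile([[1.0], [1.1], [1.2], [1.3]], (1, 1))
        xb = np.tile([[2.0], [2.1], [2.2], [2.3]], (1, 1))
        adata = self._norm_adata(xa, xb)
        out = single_cell.state_de(adata, adata.obs_names[:4], adata.obs_names[4:])
        assert out["p"].iloc[0] == pytest.approx(2 / 70, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exact_enumeration_small_n(self, seed):
        rng = np.random.default_rng(seed)
        xa = rng.normal(0, 1, size=(6, 3))
        xb = rng.normal(0.5, 1, size=(7, 3))
        adata = self._norm_adata(xa, xb)
        out = single_cell.state_de(adata, adata.obs_names[:6], adata.obs_names[6:])
        for j in range(3):
            assert out["p"].iloc[j] == pytest.approx(
                exact_ranksum_p(xa[:, j], xb[:, j]), abs=1e-12
            )

    def test_lfc_threshold_is_strict(self):
        # construct means with lfc exactly 0.2: mean expm1 ratio = e^0.2
        target = np.exp(0.2)
        mb = 1.0
        ma = target * (mb + 1.0) - 1.0
        xa = np.log1p(np.full((5, 1), ma))
        xb = np.log1p(np.full((5, 1), mb))
        adata = self._norm_adata(xa, xb)
        out = single_cell.state_de(adata, adata.obs_names[:5], adata.obs_names[5:])
        assert out["lfc"].iloc[0] == pytest.approx(0.2, abs=1e-12)
        assert not out["significant"].iloc[0]

    def test_needs_three_cells_per_side(self):
        adata = self._norm_adata(np.ones((2, 2)), np.ones((5, 2)))
        with pytest.raises(ParameterError):
            single_cell.state_de(adata, adata.obs_names[:2], adata.obs_names[2:])


class TestConcordance:
    def _result(self, lfc, sig):
        return pd.DataFrame(
            {"lfc": lfc, "significant": sig},
            index=[f"g{i}" for i in range(len(lfc))],
        )

    def test_identical_inputs_rho_one(self):
        r = self._result([1.0, 0.5, -0.5, -1.0], [True] * 4)
        assert single_cell.state_de_concordance(r, r)["rho"] == pytest.approx(1.0)

    def test_anticorrelated_rho_minus_one(self):
        a = self._result([1.0, 0.5, -0.5, -1.0], [True] * 4)
        b = self._result([-1.0, -0.5, 0.5, 1.0], [True] * 4)
        assert single_cell.state_de_concordance(a, b)["rho"] == pytest.approx(-1.0)

    def test_too_few_shared_significant(self):
        a = self._result([1.0, 0.5], [True, False])
        b = self._result([1.0, 0.5], [False, False])
        with pytest.raises(ParameterError):
            single_cell.state_de_concordance(a, b)
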