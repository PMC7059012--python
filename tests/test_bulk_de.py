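"""Bulk differential-expression units: normalization, residualization,
contrast arithmetic against a group-means oracle, and BY adjustment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amyglia import bulk_de
from amyglia.containers import BulkExperiment, ParameterError
from conftest import make_normalized


def tiny_experiment(counts, genotypes=None, ages=None):
    counts = pd.DataFrame(
        counts,
        index=[f"g{i}" for i in range(len(counts))],
        columns=[f"s{j}" for j in range(len(counts[0]))],
    )
    n = counts.shape[1]
    genotypes = genotypes or ["WT"] * (n // 2) + ["TG"] * (n - n // 2)
    ages = ages or (["4M", "10M"] * n)[:n]
    samples = pd.DataFrame(
        {
            "strain": "APP",
            "age": ages,
            "genotype": genotypes,
            "batch": "B0",
            "concentration": 100.0,
        },
        index=counts.columns,
    )
    return BulkExperiment(counts, samples)


class TestFilterLowCounts:
    def test_all_zero_gene_removed(self):
        exp = tiny_experiment([[0] * 12, [100] * 12])
        out = bulk_de.filter_low_counts(exp, min_mean=5, min_samples=10)
        assert list(out.counts.index) == ["g1"]

    def test_exactly_one_gene_passes_toy_matrix(self):
        # g0: > 5 in all 12 samples; g1: > 5 in only 9; g2: never
        rows = [[6] * 12, [6] * 9 + [0] * 3, [1] * 12]
        exp = tiny_experiment(rows)
        out = bulk_de.filter_low_counts(exp, min_mean=5, min_samples=10)
        assert list(out.counts.index) == ["g0"]

    def test_zero_thresholds_identity(self):
        exp = tiny_experiment([[0] * 12, [3] * 12])
        out = bulk_de.filter_low_counts(exp, min_mean=0, min_samples=0)
        assert out.counts.equals(exp.counts)


class TestNormalizeLogCpm:
    def test_zero_count_gives_log2_pseudocount(self):
        exp = tiny_experiment([[0] * 12, [100] * 12])
        norm = bulk_de.normalize_log_cpm(exp, pseudocount=0.5)
        assert norm.values.iloc[0, 0] == pytest.approx(-1.0)

    def test_closed_form_value(self):
        # count 10 in a library of 100 -> log2(1e5 + 0.5)
        exp = tiny_experiment([[10] * 12, [90] * 12])
        norm = bulk_de.normalize_log_cpm(exp, pseudocount=0.5)
        assert norm.values.iloc[0, 0] == pytest.approx(np.log2(1e5 + 0.5))
        assert norm.values.iloc[0, 0] == pytest.approx(16.6096, abs=1e-4)

    def test_library_size_cancellation(self):
        base = [[150] * 12, [850] * 12]
        doubled = [[300] * 12, [1700] * 12]
        n1 = bulk_de.normalize_log_cpm(tiny_experiment(base))
        n2 = bulk_de.normalize_log_cpm(tiny_experiment(doubled))
        assert np.abs(n1.values - n2.values).max().max() < 1e-3


class TestResidualize:
    def _matrix(self, values, samples):
        return make_normalized(values, samples=list(samples.index))

    def test_zero_nuisance_is_identity(self):
        exp = tiny_experiment([[10] * 12, [20] * 12])
        vals = np.tile([1.0, 2.0, 3.0, 4.0], (2, 3))
        m = self._matrix(vals, exp.samples)
        out = bulk_de.residualize_covariates(
            m, exp.samples[["batch", "concentration"]], exp.samples
        )
        assert np.abs(out.values - m.values).max().max() < 1e-8

    def test_additive_batch_offset_removed(self):
        # batch alternates orthogonally to the 2x2 design; +2 offset on B1
        genotypes = ["WT"] * 6 + ["TG"] * 6
        ages = ["4M", "4M", "4M", "10M", "10M", "10M"] * 2
        exp = tiny_experiment([[1] * 12], genotypes, ages)
        samples = exp.samples.copy()
        samples["batch"] = ["B0", "B1"] * 6
        base = np.zeros((3, 12))
        shifted = base + 2.0 * (samples["batch"] == "B1").to_numpy()
        out = bulk_de.residualize_covariates(
            self._matrix(shifted, samples), samples[["batch"]], samples
        )
        # batch effect gone: every sample back to a common level
        assert np.ptp(out.values.to_numpy()) < 1e-8

    def test_confounded_batch_raises(self):
        genotypes = ["WT"] * 6 + ["TG"] * 6
        exp = tiny_experiment([[1] * 12], genotypes)
        samples = exp.samples.copy()
        samples["batch"] = ["B0"] * 6 + ["B1"] * 6  # aliased with genotype
        with pytest.raises(ParameterError, match="aliased"):
            bulk_de.residualize_covariates(
                self._matrix(np.zeros((2, 12)), samples),
                samples[["batch"]],
                samples,
            )


def design_samples(means_by_cell, n_per_cell=3):
    rows, vals = [], []
    for (genotype, age), mu in means_by_cell.items():
        for i in range(n_per_cell):
            rows.append(
                {
                    "sample_id": f"{genotype}{age}{i}",
                    "strain": "APP",
                    "age": age,
                    "genotype": genotype,
                    "batch": "B0",
                    "concentration": 100.0,
                }
            )
            vals.append(mu)
    samples = pd.DataFrame(rows).set_index("sample_id")
    return samples, np.array(vals)


class TestTwoByTwoModel:
    CELLS = [("WT", "4M"), ("WT", "10M"), ("TG", "4M"), ("TG", "10M")]

    def _fit(self, means, style, noise=None):
        samples, mu = design_samples(dict(zip(self.CELLS, means)))
        vals = np.vstack([mu, mu + (noise if noise is not None else 0.0)])
        m = make_normalized(vals, samples=list(samples.index))
        return bulk_de.fit_two_by_two_model(m, samples, style)

    def test_noise_free_contrasts_tg10_only(self):
        res = self._fit([0, 0, 0, 3], "vs_rest")
        assert res["age"].table["lfc"].iloc[0] == pytest.approx(1.5)
        assert res["genotype"].table["lfc"].iloc[0] == pytest.approx(1.5)
        assert res["age_x_genotype"].table["lfc"].iloc[0] == pytest.approx(3.0)
        classical = self._fit([0, 0, 0, 3], "classical")
        assert classical["age_x_genotype"].table["lfc"].iloc[0] == pytest.approx(3.0)

    def test_styles_disagree_on_additive_pattern(self):
        # WT4=0, WT10=1, TG4=1, TG10=2: purely additive effects
        assert self._fit([0, 1, 1, 2], "classical")["age_x_genotype"].table[
            "lfc"
        ].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert self._fit([0, 1, 1, 2], "vs_rest")["age_x_genotype"].table[
            "lfc"
        ].iloc[0] == pytest.approx(2 - 2 / 3)

    def test_flat_groups_give_zero_contrasts_p_one(self):
        rng = np.random.default_rng(0)
        samples, mu = design_samples(dict.fromkeys(self.CELLS, 1.0))
        noise = rng.normal(0, 0.3, size=(1, len(mu)))
        # add symmetric noise per cell so group means stay exactly equal
        sym = noise - noise.reshape(1, 4, 3).mean(axis=2).repeat(3, axis=1)
        m = make_normalized(mu[None, :] + sym, samples=list(samples.index))
        res = bulk_de.fit_two_by_two_model(m, samples)
        for contrast in bulk_de.CONTRASTS:
            assert res[contrast].table["lfc"].iloc[0] == pytest.approx(0, abs=1e-12)
            assert res[contrast].table["p"].iloc[0] == pytest.approx(1.0)

    def test_empty_cell_raises(self):
        samples, mu = design_samples(dict(zip(self.CELLS[:3], [0, 1, 2])))
        m = make_normalized(mu[None, :], samples=list(samples.index))
        with pytest.raises(ParameterError, match="empty design cell"):
            bulk_de.fit_two_by_two_model(m, samples)

    def test_contrasts_match_group_means_oracle(self):
        """OLS contrast estimates equal direct group-mean arithmetic."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            samples, _ = design_samples(dict.fromkeys(self.CELLS, 0.0), 4)
            y = rng.normal(size=(5, len(samples)))
            m = make_normalized(y, samples=list(samples.index))
            res = bulk_de.fit_two_by_two_model(m, samples, "classical")
            gm = {
                cell: y[:, (samples["genotype"] == cell[0]).to_numpy()
                        & (samples["age"] == cell[1]).to_numpy()].mean(axis=1)
                for cell in self.CELLS
            }
            age = (gm[("WT", "10M")] + gm[("TG", "10M")]) / 2 - (
                gm[("WT", "4M")] + gm[("TG", "4M")]
            ) / 2
            inter = (gm[("TG", "10M")] - gm[("TG", "4M")]) - (
                gm[("WT", "10M")] - gm[("WT", "4M")]
            )
            assert np.abs(res["age"].table["lfc"].to_numpy() - age).max() < 1e-10
            assert (
                np.abs(res["age_x_genotype"].table["lfc"].to_numpy() - inter).max()
                < 1e-10
            )


class TestAdjustBY:
    @staticmethod
    def by_oracle(p):
        """Closed form: step-up BH multiplied by c(m) = sum 1/i, clipped."""
        p = np.asarray(p, float)
        m = p.size
        c = np.sum(1.0 / np.arange(1, m + 1))
        order = np.argsort(p, kind="mergesort")
        ranked = p[order] * c * m / np.arange(1, m + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(ranked, 1.0)
        return out

    def test_worked_example(self):
        adj = bulk_de.adjust_by([0.01, 0.02, 0.03])
        assert np.allclose(adj, 0.03 * 11 / 6, atol=1e-12)
        assert adj[0] == pytest.approx(0.055)

    def test_single_p_unchanged(self):
        assert bulk_de.adjust_by([0.2])[0] == pytest.approx(0.2)

    def test_ones_stay_ones(self):
        assert np.allclose(bulk_de.adjust_by([1, 1, 1]), 1.0)

    @settings(max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0, max_value=1, allow_nan=False),
                 min_size=1, max_size=40)
    )
    def test_matches_closed_form_oracle(self, p):
        assert np.allclose(bulk_de.adjust_by(p), self.by_oracle(p), atol=1e-12)

    def test_dominates_raw_p(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=500)
        assert (bulk_de.adjust_by(p) >= p - 1e-15).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ParameterError):
            bulk_de.adjust_by([0.5, 1.5])


class TestSignedRanking:
    def _result(self, lfc, p):
        tab = pd.DataFrame(
            {
                "lfc": lfc,
                "p": p,
                "p_adj": np.minimum(np.asarray(p) * 2, 1.0),
            },
            index=[f"g{i}" for i in range(len(p))],
        )
        tab["metric"] = bulk_de._signed_log10(tab["lfc"].to_numpy(),
                                              tab["p"].to_numpy())
        return bulk_de.DEResult("age_x_genotype", tab)

    def test_metric_formula_and_order(self):
        res = self._result([1.5, -1.5, 0.4], [0.01, 0.01, 1.0])
        ranked = bulk_de.signed_ranking(res)
        assert ranked.iloc[0] == pytest.approx(2.0)
        assert ranked.iloc[-1] == pytest.approx(-2.0)
        assert ranked.loc["g2"] == pytest.approx(0.0)

    def test_zero_p_floored_with_warning(self):
        with pytest.warns(UserWarning, match="floored"):
            res = self._result([1.0], [0.0])
        assert np.isfinite(res.table["metric"].iloc[0])


class TestRankCorrelation:
    def _result(self, metric, p_adj):
        tab = pd.DataFrame(
            {
                "lfc": np.sign(metric),
                "p": np.full(len(metric), 0.001),
                "p_adj": p_adj,
                "metric": metric,
            },
            index=[f"g{i}" for i in range(len(metric))],
        )
        return bulk_de.DEResult("age_x_genotype", tab)

    def test_identical_results_rho_one(self):
        a = self._result([3.0, 2, 1, -1, -2], [0.01] * 5)
        assert bulk_de.rank_correlation(a, a)["rho"] == pytest.approx(1.0)

    def test_reversed_ranking_rho_minus_one(self):
        a = self._result([5.0, 4, 3, 2, 1], [0.01] * 5)
        b = self._result([1.0, 2, 3, 4, 5], [0.01] * 5)
        assert bulk_de.rank_correlation(a, b)["rho"] == pytest.approx(-1.0)

    def test_five_gene_closed_form(self):
        a = self._result([1.0, 2, 3, 4, 5], [0.01] * 5)
        b = self._result([1.0, 3, 2, 5, 4], [0.01] * 5)
        out = bulk_de.rank_correlation(a, b)
        assert out["rho"] == pytest.approx(0.8)
        assert out["n"] == 5

    def test_subset_rule_uses_union_of_significant(self):
        a = self._result([1.0, 2, 3, 4, 5], [0.01, 0.01, 1, 1, 1])
        b = self._result([1.0, 2, 3, 4, 5], [1, 1, 0.01, 1, 1])
        assert bulk_de.rank_correlation(a, b)["n"] == 3

    def test_too_few_genes_raises(self):
        a = self._result([1.0, 2, 3], [1.0, 1.0, 1.0])
        with pytest.raises(ParameterError):
            bulk_de.rank_correlation(a, a)
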