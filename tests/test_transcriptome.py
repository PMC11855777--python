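import numpy as np
import pandas as pd
import pytest

import methimmune as mi
from methimmune.data_io import GeneSet, ValidationError
from methimmune.transcriptome import (
    checkpoint_differential,
    correlate_meth_expr,
    differential_expression,
    enrich_de_sets,
    import_external_scores,
    significance_tier,
)


@pytest.fixture()
def meth_expr():
    rng = np.random.default_rng(0)
    genes = [f"g{i}" for i in range(40)]
    ids = [f"s{i}" for i in range(30)]
    beta = mi.BetaMatrix(pd.DataFrame(rng.uniform(0.1, 0.9, (40, 30)),
                                      index=genes, columns=ids))
    labels = pd.Series(["A"] * 15 + ["B"] * 15, index=ids)
    return beta, labels


class TestCorrelation:
    def test_perfect_anticorrelation(self, meth_expr):
        beta, labels = meth_expr
        expr = 10 - beta.values  # exact negative affine map
        rep = correlate_meth_expr(beta, expr, labels, n_permutations=200, seed=1)
        assert np.allclose(rep.per_gene["r"], -1.0, atol=1e-10)
        # observed mean |r| = 1 can never be beaten by a permutation
        assert (rep.per_subtype["p_value"] <= 1 / 201 + 1e-12).all()

    def test_independent_expression_is_null(self, meth_expr):
        beta, labels = meth_expr
        rng = np.random.default_rng(2)
        expr = pd.DataFrame(rng.normal(size=beta.values.shape),
                            index=beta.values.index, columns=beta.values.columns)
        rep = correlate_meth_expr(beta, expr, labels, n_permutations=200, seed=2)
        assert (rep.per_subtype["p_value"] > 0.01).all()

    def test_planted_coupling_recovered(self, ref_panel):
        profiles = ref_panel[2].profiles
        beta, _ = mi.generate_mixtures(profiles, 60, noise_sd=0.05, seed=3)
        expr = mi.generate_expression(beta, coupling_rho=-0.5, seed=3)
        labels = pd.Series("A", index=beta.sample_ids)
        small = mi.BetaMatrix(beta.values.iloc[:200])
        rep = correlate_meth_expr(small, expr, labels, n_permutations=100, seed=3)
        mean_r = rep.per_gene["r"].mean()
        assert abs(mean_r + 0.5) < 0.05
        assert rep.per_subtype.loc[0, "baseline_mean_abs_r"] < 0.15
        assert rep.per_subtype.loc[0, "p_value"] < 0.05

    def test_zero_variance_genes_excluded(self, meth_expr):
        beta, labels = meth_expr
        vals = beta.values.copy()
        vals.iloc[0] = 0.5  # constant beta
        rep = correlate_meth_expr(mi.BetaMatrix(vals), 10 - vals, labels,
                                  n_permutations=20, seed=4)
        assert rep.n_excluded_zero_variance >= 2  # once per subtype


class TestDifferentialExpression:
    def test_identical_groups_have_no_de(self):
        rng = np.random.default_rng(5)
        expr = pd.DataFrame(rng.normal(5, 1, (100, 20)),
                            index=[f"g{i}" for i in range(100)],
                            columns=[f"s{i}" for i in range(20)])
        res = differential_expression(expr, [f"s{i}" for i in range(10)],
                                      [f"s{i}" for i in range(10, 20)])
        assert len(res.de_genes) == 0

    def test_toy_fixture_exact_selection(self):
        # 6 genes x 8 samples; exactly genes g0 and g1 are 4-fold (log2fc 2)
        rng = np.random.default_rng(6)
        base = rng.normal(5, 0.05, (6, 8))
        base[0, :4] += 2.0
        base[1, :4] -= 2.0
        base[2, :4] += 0.5            # below the fold-change filter
        expr = pd.DataFrame(base, index=[f"g{i}" for i in range(6)],
                            columns=[f"s{i}" for i in range(8)])
        res = differential_expression(expr, [f"s{i}" for i in range(4)],
                                      [f"s{i}" for i in range(4, 8)])
        assert set(res.de_genes) == {"g0", "g1"}

    def test_power_on_planted_genes(self):
        rng = np.random.default_rng(7)
        G, n = 500, 40
        expr = rng.normal(5, 0.5, (G, 2 * n))
        planted = list(range(50))
        expr[planted, :n] += 2.0
        df = pd.DataFrame(expr, index=[f"g{i}" for i in range(G)],
                          columns=[f"s{i}" for i in range(2 * n)])
        res = differential_expression(df, [f"s{i}" for i in range(n)],
                                      [f"s{i}" for i in range(n, 2 * n)])
        de = set(res.de_genes)
        hits = de & {f"g{i}" for i in planted}
        false = de - {f"g{i}" for i in planted}
        assert len(hits) >= 45 and len(false) <= 5

    def test_union_is_set_theoretic_union(self):
        res = mi.transcriptome.DEResult(
            table=pd.DataFrame(), de_genes=(), n_excluded_constant=0,
            alpha=0.05, min_abs_log2fc=1.0,
            per_cell_type={"CD4": ("g1", "g2"), "CD8": ("g2", "g3")})
        assert res.union_genes == ("g1", "g2", "g3")

    def test_too_few_samples_rejected(self):
        expr = pd.DataFrame(np.ones((3, 3)), columns=["a", "b", "c"])
        with pytest.raises(ValidationError):
            differential_expression(expr, ["a"], ["b", "c"])


class TestCheckpoint:
    def test_tier_symbols(self):
        assert significance_tier(0.2) == "ns"
        assert significance_tier(0.04) == "*"
        assert significance_tier(0.009) == "**"
        assert significance_tier(0.0009) == "***"
        assert significance_tier(5e-5) == "****"

    def test_shifted_genes_flagged(self):
        rng = np.random.default_rng(8)
        genes = [f"icg{i}" for i in range(20)]
        ids = [f"s{i}" for i in range(120)]
        expr = pd.DataFrame(rng.normal(5, 1, (20, 120)), index=genes, columns=ids)
        labels = pd.Series(["A"] * 60 + ["B"] * 60, index=ids)
        expr.loc[genes[:5], labels == "B"] += 1.5
        table = checkpoint_differential(expr, labels, genes)
        flagged = table.set_index("gene_id")["tier"]
        assert (flagged[genes[:5]] != "ns").all()
        assert (flagged[genes[10:]] == "ns").mean() > 0.8

    def test_missing_gene_reported_not_tested(self):
        rng = np.random.default_rng(9)
        expr = pd.DataFrame(rng.normal(size=(2, 10)), index=["g1", "g2"],
                            columns=[f"s{i}" for i in range(10)])
        labels = pd.Series(["A"] * 5 + ["B"] * 5,
                           index=[f"s{i}" for i in range(10)])
        table = checkpoint_differential(expr, labels, ["g1", "gX"])
        row = table.set_index("gene_id").loc["gX"]
        assert row["flag"] == "missing" and np.isnan(row["p_value"])

    def test_single_subtype_rejected(self):
        expr = pd.DataFrame(np.ones((1, 4)), index=["g1"],
                            columns=list("abcd"))
        labels = pd.Series(["A"] * 4, index=list("abcd"))
        with pytest.raises(ValidationError):
            checkpoint_differential(expr, labels, ["g1"])


class TestEnrichDE:
    def _de(self, genes):
        return mi.transcriptome.DEResult(
            table=pd.DataFrame(), de_genes=tuple(genes),
            n_excluded_constant=0, alpha=0.05, min_abs_log2fc=1.0)

    def test_planted_enrichment_ranks_first(self):
        universe = [f"g{i}" for i in range(100)]
        target = GeneSet("target", "", tuple(universe[:20]))
        decoy = GeneSet("decoy", "", tuple(universe[50:70]))
        table = enrich_de_sets(self._de(universe[:15]), [target, decoy], universe)
        assert table.loc[0, "set_name"] == "target"
        assert table.loc[0, "q_value"] < 0.05

    def test_empty_de_set_vacuous(self):
        universe = [f"g{i}" for i in range(20)]
        table = enrich_de_sets(self._de([]),
                               [GeneSet("S", "", tuple(universe[:5]))], universe)
        assert np.allclose(table["p_value"], 1.0)

    def test_disjoint_de_set_has_no_overlap(self):
        universe = [f"g{i}" for i in range(20)]
        table = enrich_de_sets(self._de(universe[10:]),
                               [GeneSet("S", "", tuple(universe[:5]))], universe)
        assert (table["overlap"] == 0).all()


class TestExternalScores:
    def _scores(self, values, ids):
        return pd.DataFrame({"sample_id": ids, "score": values})

    def test_identical_distributions_not_significant(self):
        rng = np.random.default_rng(10)
        ids = [f"s{i}" for i in range(80)]
        labels = pd.Series(["A"] * 40 + ["B"] * 40, index=ids)
        res = import_external_scores(self._scores(rng.normal(0, 1, 80), ids), labels)
        assert res["p_value"] > 0.01

    def test_shifted_subtype_flagged(self):
        rng = np.random.default_rng(11)
        ids = [f"s{i}" for i in range(80)]
        labels = pd.Series(["A"] * 40 + ["B"] * 40, index=ids)
        vals = np.concatenate([rng.normal(0, 1, 40), rng.normal(2, 1, 40)])
        res = import_external_scores(self._scores(vals, ids), labels)
        assert res["tier"] != "ns"
        assert (res["pairwise"]["q_value"] < 0.05).all()

    def test_half_missing_dropped_with_count(self):
        rng = np.random.default_rng(12)
        ids = [f"s{i}" for i in range(40)]
        labels = pd.Series(["A"] * 20 + ["B"] * 20, index=ids)
        res = import_external_scores(
            self._scores(rng.normal(0, 1, 20), ids[::2]), labels)
        assert res["n_dropped"] == 20
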