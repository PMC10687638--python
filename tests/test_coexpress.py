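import numpy as np
import pandas as pd
import pytest

import homeotrip as ht
from homeotrip.containers import ExpressionMatrix, HomeotripError


def _tpm(values, columns=None):
    df = pd.DataFrame(values) if columns is None else pd.DataFrame(values, columns=columns)
    df.index = [f"g{i}" for i in range(len(df))]
    return ExpressionMatrix(df.astype(float), "TPM")


class TestVariableGeneFilter:
    def test_top_fraction_keeps_highest_variance(self, rng):
        vals = {f"s{j}": rng.uniform(2, 10, 10) for j in range(5)}
        expr = _tpm(vals)
        expr.values.loc["g0"] = [2.0, 50.0, 2.0, 80.0, 2.0]
        expr.values.loc["g1"] = [2.0, 40.0, 3.0, 60.0, 2.0]
        kept = ht.filter_variable_genes(expr, top_fraction=0.2)
        assert set(kept) == {"g0", "g1"}

    def test_constant_gene_never_selected(self):
        expr = _tpm({"s0": [5.0, 5.0], "s1": [5.0, 9.0], "s2": [5.0, 2.0]})
        kept = ht.filter_variable_genes(expr, top_fraction=0.5)
        assert kept == ["g1"]

    def test_all_below_tpm_threshold_raises(self):
        expr = _tpm({"s0": [0.5, 0.9], "s1": [0.2, 0.8]})
        with pytest.raises(HomeotripError, match="TPM"):
            ht.filter_variable_genes(expr)


class TestEdges:
    def test_perfect_scaling_makes_edge(self):
        a = np.array([1.0, 4.0, 2.0, 8.0])
        expr = _tpm({"s0": [a[0], 2 * a[0]], "s1": [a[1], 2 * a[1]], "s2": [a[2], 2 * a[2]], "s3": [a[3], 2 * a[3]]})
        edges = ht.correlation_edges(expr, log_transform=False)
        assert len(edges) == 1
        assert edges["r"].iloc[0] == pytest.approx(1.0)

    def test_anticorrelation_makes_no_edge(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        expr = _tpm({f"s{j}": [x[j], 5 - x[j]] for j in range(4)})
        edges = ht.correlation_edges(expr, log_transform=False)
        assert len(edges) == 0

    def test_hand_computed_pearson(self):
        expr = _tpm({f"s{j}": row for j, row in enumerate(zip([1, 2, 3, 4], [1, 2, 3, 5]))})
        edges = ht.correlation_edges(expr, log_transform=False)
        assert len(edges) == 1
        # cov = 1.625, sd_x = sqrt(1.25), sd_y = sqrt(2.1875) -> r = 0.98271
        assert edges["r"].iloc[0] == pytest.approx(0.9827076, abs=1e-6)

    def test_edge_list_has_no_self_or_duplicate_pairs(self, rng):
        expr = _tpm({f"s{j}": rng.uniform(1, 50, 20) for j in range(6)})
        edges = ht.correlation_edges(expr)
        pairs = set(map(frozenset, zip(edges["geneA"], edges["geneB"])))
        assert len(pairs) == len(edges)
        assert all(len(p) == 2 for p in pairs)


class TestModules:
    def _clique_edges(self, prefix, n):
        genes = [f"{prefix}{i}" for i in range(n)]
        return [(a, b) for i, a in enumerate(genes) for b in genes[i + 1:]]

    def test_two_disjoint_cliques_give_two_modules(self):
        pairs = self._clique_edges("a", 5) + self._clique_edges("b", 5)
        edges = pd.DataFrame(pairs, columns=["geneA", "geneB"])
        modules = ht.detect_modules(edges, seed=1)
        assert modules.nunique() == 2
        assert modules.value_counts().tolist() == [5, 5]
        assert modules["a0"] != modules["b0"]

    def test_single_edge_is_one_module_at_default_resolution(self):
        edges = pd.DataFrame({"geneA": ["x"], "geneB": ["y"]})
        modules = ht.detect_modules(edges, seed=0)
        assert modules.nunique() == 1

    def test_same_seed_identical_partition(self, rng):
        expr = _tpm({f"s{j}": rng.uniform(1, 50, 40) for j in range(8)})
        edges = ht.correlation_edges(expr)
        m1 = ht.detect_modules(edges, seed=7)
        m2 = ht.detect_modules(edges, seed=7)
        pd.testing.assert_series_equal(m1, m2)

    def test_partition_covers_filtered_nodes(self):
        edges = pd.DataFrame({"geneA": ["x"], "geneB": ["y"]})
        modules = ht.detect_modules(edges, nodes=["x", "y", "lonely"], seed=0)
        assert set(modules.index) == {"x", "y", "lonely"}


class TestModuleDeSummary:
    def test_counts_up_and_down(self):
        modules = pd.Series([0] * 10, index=[f"g{i}" for i in range(10)])
        de = pd.DataFrame(
            {"call": ["up"] * 3 + ["down"] * 2 + ["ns"] * 4},
            index=[f"g{i}" for i in range(9)],  # g9 missing from DE table
        )
        summary = ht.module_de_summary(modules, de)
        row = summary.loc[0]
        assert (row["size"], row["n_up"], row["n_down"]) == (10, 3, 2)

    def test_empty_modules_give_empty_summary(self):
        summary = ht.module_de_summary(pd.Series(dtype=int), pd.DataFrame({"call": []}))
        assert len(summary) == 0


def test_planted_blocks_land_in_distinct_modules():
    tpm = ht.simulate_coexpression_blocks(n_blocks=2, genes_per_block=50, seed=4)
    expr = ExpressionMatrix(tpm, "TPM")
    genes = ht.filter_variable_genes(expr, min_tpm=1.0, top_fraction=0.7)
    edges = ht.correlation_edges(expr, genes)
    assert (edges["r"] > 0.7).all()
    modules = ht.detect_modules(edges, nodes=genes, seed=4)
    block0 = [g for g in genes if g.startswith("BLOCK0")]
    block1 = [g for g in genes if g.startswith("BLOCK1")]
    assert modules.loc[block0].nunique() == 1
    assert modules.loc[block1].nunique() == 1
    assert modules.loc[block0[0]] != modules.loc[block1[0]]
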