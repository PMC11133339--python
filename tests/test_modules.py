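import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from triaxis.modules import (NetworkParams, detect_modules, hub_genes,
                             module_differential_expression,
                             module_expression, module_graph, residualize,
                             select_soft_power, signed_tom,
                             tom_from_adjacency)


def tom_bruteforce(a):
    """Literal triple-loop signed TOM."""
    m = a.shape[0]
    tom = np.eye(m)
    for i in range(m):
        for j in range(m):
            if i == j:
                continue
            L = sum(a[i, u] * a[u, j] for u in range(m) if u not in (i, j))
            ki = sum(a[i, u] for u in range(m) if u != i)
            kj = sum(a[j, u] for u in range(m) if u != j)
            tom[i, j] = (L + a[i, j]) / (min(ki, kj) + 1 - a[i, j])
    return tom


def planted_blocks(rng, n=200, block_sizes=(30, 30), r=0.8, n_noise=30):
    rows, truth = [], []
    for b, size in enumerate(block_sizes, start=1):
        z = rng.normal(size=n)
        rows.append(np.sqrt(r) * z[None, :]
                    + np.sqrt(1 - r) * rng.normal(size=(size, n)))
        truth += [b] * size
    rows.append(rng.normal(size=(n_noise, n)))
    truth += [0] * n_noise
    X = np.vstack(rows)
    ids = [f"g{i:03d}" for i in range(X.shape[0])]
    return pd.DataFrame(X, index=ids), truth


class TestAdjacencyAndTom:
    def test_adjacency_endpoints(self):
        x = np.array([[1.0, 2, 3, 4], [2, 4, 6, 8], [4, 3, 2, 1]])
        tom = signed_tom(pd.DataFrame(x), power=6)
        # perfectly correlated pair -> adjacency 1 -> TOM 1
        assert tom[0, 1] == pytest.approx(1.0)
        # perfectly anticorrelated -> adjacency 0
        r = np.corrcoef(x)
        a = ((1 + r) / 2) ** 6
        assert a[0, 2] == pytest.approx(0.0)

    def test_two_node_tom_equals_adjacency(self):
        a = np.array([[1.0, 0.37], [0.37, 1.0]])
        tom = tom_from_adjacency(a)
        assert tom[0, 1] == pytest.approx(0.37)

    @pytest.mark.parametrize("m", [3, 7, 12])
    def test_matches_triple_loop_oracle(self, m, rng):
        r = np.corrcoef(rng.normal(size=(m, 40)))
        a = ((1 + r) / 2) ** 4
        np.fill_diagonal(a, 1.0)
        np.testing.assert_allclose(tom_from_adjacency(a), tom_bruteforce(a),
                                   atol=1e-10)

    def test_tom_bounded_and_symmetric(self, rng):
        tom = signed_tom(pd.DataFrame(rng.normal(size=(20, 50))), power=6)
        assert np.all((tom >= 0) & (tom <= 1))
        np.testing.assert_allclose(tom, tom.T)


class TestSoftPower:
    def test_planted_hub_structure_reaches_target(self, rng):
        # heavy-tailed loadings on a shared latent give hub-like topology
        n, G = 200, 150
        lam = rng.uniform(0, 1, G) ** 2
        z = rng.normal(size=n)
        X = (lam[:, None] * z[None, :]
             + np.sqrt(1 - np.clip(lam ** 2, 0, 0.99))[:, None]
             * rng.normal(size=(G, n)))
        with warnings.catch_warnings():
            warnings.simplefilter("error")  # no fallback warning expected
            p = select_soft_power(pd.DataFrame(X))
        assert 1 <= p <= 20

    def test_fallback_warns_and_returns_argmax(self, rng):
        expr = pd.DataFrame(rng.normal(size=(40, 10)))
        params = NetworkParams(powers=(1,))
        with pytest.warns(UserWarning, match="argmax"):
            p = select_soft_power(expr, params)
        assert p == 1

    def test_invariant_to_global_scaling(self, rng):
        expr, _ = planted_blocks(rng, n=100)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert select_soft_power(expr) == select_soft_power(expr * 2.0)


class TestDetectModules:
    def test_recovers_planted_blocks(self, rng):
        expr, truth = planted_blocks(rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = select_soft_power(expr)
        asg = detect_modules(signed_tom(expr, p), gene_ids=list(expr.index))
        assert len(set(asg) - {0}) == 2
        assert adjusted_rand_score(truth, asg.tolist()) > 0.9

    def test_small_block_pruned_to_zero(self, rng):
        expr, truth = planted_blocks(rng, block_sizes=(30, 10), n_noise=20)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = select_soft_power(expr)
        asg = detect_modules(signed_tom(expr, p), gene_ids=list(expr.index))
        small_block = [g for g, t in zip(expr.index, truth) if t == 2]
        assert all(asg[g] == 0 for g in small_block)

    def test_gene_permutation_equivariant(self, rng):
        expr, _ = planted_blocks(rng, n=120)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = select_soft_power(expr)
        asg = detect_modules(signed_tom(expr, p), gene_ids=list(expr.index))
        perm = rng.permutation(len(expr))
        expr2 = expr.iloc[perm]
        asg2 = detect_modules(signed_tom(expr2, p),
                              gene_ids=list(expr2.index))
        # same partition up to relabeling
        assert adjusted_rand_score(asg[expr2.index].tolist(),
                                   asg2.tolist()) == pytest.approx(1.0)


class TestModuleExpression:
    def _samples(self, n, rng):
        return pd.DataFrame({
            "case": rng.integers(0, 2, n),
            "sex": rng.choice(["F", "M"], n),
            "batch": rng.choice(["B1", "B2"], n),
            "rin": rng.normal(7, 1, n),
            "gc": rng.normal(0.47, 0.02, n),
        }, index=[f"S{i}" for i in range(n)])

    def test_single_gene_module_passthrough_no_nuisance(self, rng):
        n = 20
        samples = self._samples(n, rng)
        expr = pd.DataFrame(rng.normal(size=(1, n)), index=["g1"],
                            columns=samples.index)
        asg = pd.Series([1], index=["g1"])
        me = module_expression(expr, samples, asg, nuisance=())
        np.testing.assert_allclose(me.loc[1], expr.loc["g1"])

    def test_empty_nuisance_is_plain_mean(self, rng):
        n = 15
        samples = self._samples(n, rng)
        expr = pd.DataFrame(rng.normal(size=(4, n)),
                            index=list("abcd"), columns=samples.index)
        asg = pd.Series([1, 1, 1, 1], index=list("abcd"))
        me = module_expression(expr, samples, asg, nuisance=())
        np.testing.assert_allclose(me.loc[1], expr.mean(axis=0))

    def test_planted_batch_shift_fully_removed(self, rng):
        n = 40
        samples = self._samples(n, rng)
        batch_shift = (samples["batch"] == "B2").to_numpy(float) * 3.0
        expr = pd.DataFrame(np.tile(batch_shift, (5, 1)) + 1.0,
                            index=list("abcde"), columns=samples.index)
        asg = pd.Series([1] * 5, index=list("abcde"))
        me = module_expression(expr, samples, asg, nuisance=("batch",))
        b1 = me.loc[1, samples["batch"] == "B1"].mean()
        b2 = me.loc[1, samples["batch"] == "B2"].mean()
        assert abs(b1 - b2) < 1e-8


class TestModuleDE:
    def test_planted_module_shift_recovered(self, cohort):
        design, samples, _ = cohort
        rng = np.random.default_rng(1)
        n = len(samples)
        case = samples["case"].to_numpy(float)
        mexpr = pd.DataFrame(
            np.vstack([0.5 * case + rng.normal(0, 0.4, n),
                       rng.normal(0, 0.4, n),
                       rng.normal(0, 0.4, n)]),
            index=[1, 2, 3], columns=samples.index)
        de = module_differential_expression(mexpr, samples)
        row = de.set_index("module").loc[1]
        assert row["log2fc"] == pytest.approx(0.5, abs=0.15)
        assert row["q"] < 0.01
        assert not de["ols_fallback"].any()

    def test_single_module_falls_back_to_ols(self, cohort):
        _, samples, _ = cohort
        rng = np.random.default_rng(2)
        mexpr = pd.DataFrame(rng.normal(size=(1, len(samples))),
                             index=[1], columns=samples.index)
        de = module_differential_expression(mexpr, samples)
        assert de["ols_fallback"].all()


class TestHubGenes:
    def test_three_gene_connectivity_example(self):
        a = np.array([[1.0, 0.9, 0.9],
                      [0.9, 1.0, 0.1],
                      [0.9, 0.1, 1.0]])
        asg = pd.Series([1, 1, 1], index=["gA", "gB", "gC"])
        hubs = hub_genes(asg, adjacency=a, gene_ids=["gA", "gB", "gC"])
        assert hubs[1] == "gA"  # k = 1.8 vs 1.0, 1.0

    def test_tie_breaks_lexicographically(self):
        a = np.array([[1.0, 0.5], [0.5, 1.0]])
        asg = pd.Series([1, 1], index=["gZ", "gA"])
        hubs = hub_genes(asg, adjacency=a, gene_ids=["gZ", "gA"])
        assert hubs[1] == "gA"

    def test_external_interaction_table_degree(self):
        asg = pd.Series([1, 1, 1], index=["gA", "gB", "gC"])
        table = pd.DataFrame({"gene_a": ["gA", "gA"],
                              "gene_b": ["gB", "gC"],
                              "score": [0.5, 0.1]})
        hubs = hub_genes(asg, interaction_table=table)
        # only the 0.5 edge counts; gA and gB tie at degree 1 -> gA
        assert hubs[1] == "gA"


class TestModuleGraph:
    def test_threshold_strict_and_positive_only(self, rng):
        n = 400
        a = rng.normal(size=n)
        rows = {"m1": a, "m2": a + rng.normal(0, 0.1, n), "m3": -a}
        me = pd.DataFrame(rows).T
        edges = module_graph(me)
        pairs = set(map(tuple, edges[["module_a", "module_b"]].to_numpy()))
        assert ("m1", "m2") in pairs
        assert not any("m3" in p for p in pairs)  # anti-correlated excluded

    def test_exactly_half_correlation_excluded(self):
        me = pd.DataFrame([[1.0, 2, 3, 4]] * 2, index=["a", "b"])
        # construct r exactly 0.5 via explicit rows
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, -1.0, -1.0, 1.0])
        z = x + y  # corr(x, z) = 0.7071; build a true 0.5 pair instead
        u = np.array([1.0, 1.0, -1.0, -1.0])
        v = np.array([1.0, -1.0, 1.0, -1.0])
        w = (u + v) / np.sqrt(2)
        me = pd.DataFrame({"u": u, "w": w}).T
        r = np.corrcoef(me.to_numpy())[0, 1]
        assert r == pytest.approx(1 / np.sqrt(2))
        edges = module_graph(me, r_threshold=r)
        assert edges.empty  # strictly greater required

    def test_identical_rows_edge_weight_one(self):
        me = pd.DataFrame([[1.0, 2, 3], [1.0, 2, 3]], index=["a", "b"])
        edges = module_graph(me)
        assert edges.iloc[0]["r"] == pytest.approx(1.0)
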