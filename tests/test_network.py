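"""Co-expression network construction: oracles, invariants, planted recovery."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from brainmod.network import (
    NetworkParams,
    UNASSIGNED,
    build_network,
    cluster_and_cut,
    collapse_probes,
    connectivity,
    dataset_concordance,
    eigengene_set,
    merge_modules,
    module_eigengene,
    module_membership,
    region_profile,
    select_representative_regions,
    soft_adjacency,
    tom,
    top_connections,
)
from brainmod.synth import SynthConfig, gen_expression, sample_metadata


def brute_force_tom(a):
    """O(n^3) oracle for the topological overlap matrix."""
    n = a.shape[0]
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    t = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
            t[i, j] = (l + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return t


class TestAdjacency:
    def test_even_power_kills_sign(self):
        X = np.vstack([np.arange(10.0), np.arange(10.0) * -1, np.arange(10.0) * 2])
        adj = soft_adjacency(X, 6)
        assert adj[0, 1] == pytest.approx(1.0)  # cor = -1
        assert adj[0, 2] == pytest.approx(1.0)  # cor = +1

    def test_half_correlation_sixth_power(self):
        # construct two genes with correlation exactly +-0.5
        rng = np.random.default_rng(0)
        z = rng.standard_normal((2, 100_000))
        x = z[0]
        y = 0.5 * z[0] + np.sqrt(0.75) * z[1]
        adj = soft_adjacency(np.vstack([x, y]), 6)
        assert adj[0, 1] == pytest.approx(0.5**6, abs=2e-3)
        adj_neg = soft_adjacency(np.vstack([x, -y]), 6)
        assert adj_neg[0, 1] == pytest.approx(0.015625, abs=2e-3)

    def test_symmetry_and_range(self, rng):
        adj = soft_adjacency(rng.standard_normal((20, 10)), 6)
        assert np.allclose(adj, adj.T)
        assert adj.min() >= 0 and adj.max() <= 1

    def test_zero_variance_gene_zeroed(self, rng):
        X = rng.standard_normal((5, 20))
        X[2] = 3.0
        adj = soft_adjacency(X, 6)
        assert (adj[2] == 0).all() and (adj[:, 2] == 0).all()


class TestConnectivity:
    def test_all_zero(self):
        assert (connectivity(np.zeros((4, 4))) == 0).all()

    def test_three_nodes_half(self):
        a = np.full((3, 3), 0.5)
        np.fill_diagonal(a, 0.0)
        assert connectivity(a) == pytest.approx([1.0, 1.0, 1.0])

    def test_matches_row_sum_oracle(self, rng):
        a = rng.uniform(0, 1, (50, 50))
        a = (a + a.T) / 2
        expected = np.array([sum(a[i, j] for j in range(50) if j != i) for i in range(50)])
        assert connectivity(a) == pytest.approx(expected)


class TestTom:
    def test_no_shared_neighbors(self):
        a = np.zeros((4, 4))
        t = tom(a)
        assert np.allclose(t, np.eye(4))

    def test_three_node_hand_computation(self):
        a = np.full((3, 3), 0.5)
        np.fill_diagonal(a, 0.0)
        t = tom(a)
        # l_12 = a_13 a_32 = 0.25; k = 1; (0.25 + 0.5)/(1 + 1 - 0.5) = 0.5
        assert t[0, 1] == pytest.approx(0.5)

    @pytest.mark.parametrize("n", [30, 50])
    def test_matches_brute_force_oracle(self, rng, n):
        a = rng.uniform(0, 1, (n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        assert np.abs(tom(a) - brute_force_tom(a)).max() < 1e-10

    def test_symmetric_unit_interval(self, rng):
        a = rng.uniform(0, 1, (40, 40))
        a = (a + a.T) / 2
        t = tom(a)
        assert np.allclose(t, t.T)
        assert t.min() >= 0 and t.max() <= 1


class TestCollapseProbes:
    def _annotated(self, expr, genes, refseq=None):
        ann = pd.DataFrame({"gene": genes}, index=expr.index)
        ann["refseq"] = True if refseq is None else refseq
        return ann

    def test_single_probe_passes_through(self, rng):
        expr = pd.DataFrame(rng.standard_normal((3, 10)), index=["p1", "p2", "p3"])
        ann = self._annotated(expr, ["gA", "gB", "gC"])
        out = collapse_probes(expr, ann)
        assert np.allclose(out.loc["gA"], expr.loc["p1"])

    def test_two_probes_highest_mean_wins(self, rng):
        expr = pd.DataFrame(
            np.vstack([np.full(10, 3.0), np.full(10, 5.0)]), index=["p1", "p2"]
        )
        out = collapse_probes(expr, self._annotated(expr, ["gA", "gA"]))
        assert np.allclose(out.loc["gA"], 5.0)

    def test_three_probes_highest_connectivity_wins(self):
        cfg = SynthConfig(n_genes=60, n_samples=80, module_sizes=(50,), noise_sd=0.2, seed=13)
        expr, truth = gen_expression(cfg)
        rng = np.random.default_rng(1)
        member = truth.genes_in("mod01")[0]
        # probe A tracks the module; probes B, C are noise
        probes = pd.DataFrame(
            np.vstack(
                [
                    expr.loc[member].to_numpy(),
                    rng.standard_normal(cfg.n_samples),
                    rng.standard_normal(cfg.n_samples),
                ]
            ),
            index=["pA", "pB", "pC"],
            columns=expr.columns,
        )
        combined = pd.concat([expr.drop(index=member), probes])
        ann = pd.DataFrame(
            {
                "gene": [g for g in expr.index if g != member] + [member] * 3,
                "refseq": True,
            },
            index=combined.index,
        )
        out = collapse_probes(combined, ann)
        assert np.allclose(out.loc[member], probes.loc["pA"])

    def test_non_refseq_probes_dropped(self, rng):
        expr = pd.DataFrame(rng.standard_normal((2, 8)), index=["p1", "p2"])
        out = collapse_probes(expr, self._annotated(expr, ["gA", "gB"], [True, False]))
        assert list(out.index) == ["gA"]


class TestClusterAndCut:
    def test_noisy_planted_blocks_recovered(self):
        cfg = SynthConfig(
            n_genes=150, n_samples=150, module_sizes=(40, 40), noise_sd=0.4, seed=2
        )
        expr, truth = gen_expression(cfg)
        net = build_network(expr)
        lab = net["labels"]
        tl = pd.Series(truth.module_of).loc[lab.index]
        assert adjusted_rand_score(tl, lab) >= 0.9
        assert lab[lab != UNASSIGNED].nunique() == 2

    def test_small_planted_block_left_unassigned(self):
        cfg = SynthConfig(
            n_genes=120, n_samples=100, module_sizes=(40, 10), noise_sd=0.1, seed=6
        )
        expr, truth = gen_expression(cfg)
        net = build_network(expr)
        small = truth.genes_in("mod02")
        assert (net["labels"].loc[small] == UNASSIGNED).all()

    def test_gene_order_invariance(self):
        cfg = SynthConfig(
            n_genes=120, n_samples=100, module_sizes=(40, 35), noise_sd=0.3, seed=8
        )
        expr, _ = gen_expression(cfg)
        net1 = build_network(expr)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(expr))
        net2 = build_network(expr.iloc[perm])
        lab1 = net1["labels"]
        lab2 = net2["labels"].loc[lab1.index]
        assert adjusted_rand_score(lab1, lab2) == pytest.approx(1.0)

    def test_fewer_genes_than_min_size_all_unassigned(self, rng):
        d = rng.uniform(0, 1, (10, 10))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        _, lab = cluster_and_cut(d, NetworkParams())
        assert (lab == UNASSIGNED).all()


class TestEigengene:
    def test_identical_rows(self):
        X = np.tile(np.arange(8.0), (5, 1))
        e, varexp = module_eigengene(X)
        assert varexp == pytest.approx(1.0)
        r = np.corrcoef(e, X[0])[0, 1]
        assert r == pytest.approx(1.0)

    def test_anticorrelated_pair(self):
        x = np.arange(10.0)
        X = np.vstack([x, -x + 3.0])
        e, varexp = module_eigengene(X)
        assert varexp == pytest.approx(1.0)

    def test_matches_eigendecomposition_oracle(self, rng):
        X = rng.standard_normal((20, 40))
        e, varexp = module_eigengene(X)
        Z = (X - X.mean(1, keepdims=True)) / X.std(1, keepdims=True)
        w, v = np.linalg.eigh(Z.T @ Z)
        top = v[:, -1]
        assert abs(abs(np.corrcoef(e, top)[0, 1]) - 1.0) < 1e-10
        assert varexp == pytest.approx(w[-1] / w.sum())

    def test_sign_follows_mean_profile(self, rng):
        X = rng.standard_normal((10, 30)) + 5 * np.sin(np.arange(30))
        e, _ = module_eigengene(X)
        assert np.corrcoef(e, X.mean(0))[0, 1] >= 0


class TestModuleMembership:
    def test_gene_equal_to_eigengene(self, small_data):
        expr, truth = small_data
        labels = pd.Series(truth.module_of)
        eg = eigengene_set(expr, labels)
        probe = expr.copy()
        probe.loc["synthetic_eigengene_probe"] = eg["mod01"].to_numpy()
        kme = module_membership(probe, eg)
        assert kme.loc["synthetic_eigengene_probe", "mod01"] == pytest.approx(1.0)

    def test_own_module_kme_beats_background(self, small_data):
        expr, truth = small_data
        labels = pd.Series(truth.module_of)
        eg = eigengene_set(expr, labels)
        kme = module_membership(expr, eg)
        own = kme.loc[truth.genes_in("mod01"), "mod01"].abs().mean()
        bg = kme.loc[truth.genes_in(UNASSIGNED), "mod01"].abs().mean()
        assert own > bg + 0.3

    def test_kme_bounded(self, small_data):
        expr, truth = small_data
        eg = eigengene_set(expr, pd.Series(truth.module_of))
        kme = module_membership(expr, eg)
        assert kme.to_numpy().min() >= -1 and kme.to_numpy().max() <= 1


class TestMergeModules:
    def test_identical_eigengenes_merge(self, small_data):
        expr, truth = small_data
        labels = pd.Series(truth.module_of).copy()
        mod1 = truth.genes_in("mod01")
        # artificially split one planted module in two
        labels.loc[mod1[: len(mod1) // 2]] = "mod01a"
        labels.loc[mod1[len(mod1) // 2 :]] = "mod01b"
        merged = merge_modules(expr, labels, 0.3)
        assert merged.loc[mod1].nunique() == 1

    def test_orthogonal_eigengenes_unchanged(self, small_data):
        expr, truth = small_data
        labels = pd.Series(truth.module_of)
        merged = merge_modules(expr, labels, 0.3)
        assert (merged.loc[truth.genes_in("mod01")] != merged.loc[truth.genes_in("mod02")].iloc[0]).all()
        assert merged.nunique() == labels.nunique()


class TestTopConnections:
    def test_small_module_exhausts_edges(self, rng):
        t = rng.uniform(0, 1, (5, 5))
        t = (t + t.T) / 2
        genes = [f"g{i}" for i in range(5)]
        edges, hubs = top_connections(t, genes, genes[:3], top_edges=150)
        assert len(edges) == 3

    def test_tie_break_is_deterministic(self):
        t = np.full((4, 4), 0.5)
        genes = ["gA", "gB", "gC", "gD"]
        edges, _ = top_connections(t, genes, genes, top_edges=2)
        assert edges[["gene_a", "gene_b"]].values.tolist() == [["gA", "gB"], ["gA", "gC"]]

    def test_planted_hub_is_found(self):
        cfg = SynthConfig(
            n_genes=60,
            n_samples=120,
            module_sizes=(50,),
            loading_range=(0.6, 0.6),
            noise_sd=0.3,
            seed=19,
        )
        expr, truth = gen_expression(cfg)
        hub_gene = truth.genes_in("mod01")[0]
        # boost one gene to loading ~1 by denoising its profile toward the factor
        others = truth.genes_in("mod01")[1:]
        factor_proxy = expr.loc[others].mean(axis=0)
        expr.loc[hub_gene] = factor_proxy / factor_proxy.std()
        net = build_network(expr)
        edges, hubs = top_connections(
            net["tom"], list(expr.index), truth.genes_in("mod01"), 150
        )
        assert hub_gene in hubs


class TestRegions:
    def _profiles(self, small_data, small_config):
        expr, truth = small_data
        meta = sample_metadata(small_config)
        eg = eigengene_set(expr, pd.Series(truth.module_of))
        return region_profile(eg, meta)

    def test_top_regions_shape(self, small_data, small_config):
        means, top = self._profiles(small_data, small_config)
        assert all(len(v) == 10 for v in top.values())
        assert set(means.columns) == {"mod01", "mod02"}

    def test_request_all_regions(self, small_data, small_config):
        means, _ = self._profiles(small_data, small_config)
        assert select_representative_regions(means, n=len(means)) == list(means.index)

    def test_highest_sd_region_first(self):
        profiles = pd.DataFrame(
            {"m1": [0.1, 5.0, 0.2], "m2": [0.1, -5.0, 0.2]},
            index=["r1", "r2", "r3"],
        )
        assert select_representative_regions(profiles, 2)[0] == "r2"

    def test_duplicate_region_deprioritized(self):
        profiles = pd.DataFrame(
            {
                "m1": [5.0, 5.0, 1.0, 0.0],
                "m2": [-5.0, -5.0, 0.5, 2.0],
                "m3": [1.0, 1.0, -3.0, 0.3],
            },
            index=["r1", "r1dup", "r2", "r3"],
        )
        chosen = select_representative_regions(profiles, 3)
        assert not {"r1", "r1dup"} <= set(chosen)


class TestConcordance:
    def test_identical_datasets(self, small_data):
        expr, _ = small_data
        r_expr, r_conn = dataset_concordance(expr, expr)
        assert r_expr == pytest.approx(1.0)
        assert r_conn == pytest.approx(1.0)

    def test_noise_sweep_is_monotone(self, small_data, rng):
        expr, _ = small_data
        rs = []
        for sd in (0.0, 1.0, 50.0):
            noisy = expr + rng.standard_normal(expr.shape) * sd
            r_expr, _ = dataset_concordance(expr, noisy)
            rs.append(r_expr)
        assert rs[0] > rs[1] > rs[2]
        assert abs(rs[2]) < 0.2

    def test_too_few_shared_genes(self, small_data):
        expr, _ = small_data
        with pytest.raises(ValueError, match="shared"):
            dataset_concordance(expr.iloc[:2], expr.iloc[:2])


class TestPipelineInvariants:
    def test_zero_noise_partition_exact(self):
        cfg = SynthConfig(
            n_genes=130, n_samples=80, module_sizes=(40, 40), noise_sd=0.0, seed=23
        )
        expr, truth = gen_expression(cfg)
        net = build_network(expr)
        tl = pd.Series(truth.module_of).loc[net["labels"].index]
        assert adjusted_rand_score(tl, net["labels"]) == pytest.approx(1.0)

    def test_variance_explained_decreases_with_noise(self):
        vals = []
        for sd in (0.2, 0.6, 1.2):
            cfg = SynthConfig(
                n_genes=80, n_samples=80, module_sizes=(40,), noise_sd=sd, seed=29
            )
            expr, truth = gen_expression(cfg)
            _, varexp = module_eigengene(expr.loc[truth.genes_in("mod01")].to_numpy())
            vals.append(varexp)
        assert vals[0] > vals[1] > vals[2]
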