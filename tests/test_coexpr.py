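"""Co-expression networks: adjacency, TOM, module detection, MI/DPI, hubs."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from crossconcord import coexpr, synthgen
from crossconcord.synthgen import ModuleSpec, SyntheticDesign


def frame(arr, prefix="g"):
    ids = [f"{prefix}{i:03d}" for i in range(arr.shape[0])]
    return pd.DataFrame(arr, index=ids, columns=[f"s{j}" for j in range(arr.shape[1])])


class TestSelectVariableGenes:
    def test_identity_when_n_equals_total(self, rng):
        values = frame(rng.normal(size=(20, 10)))
        assert set(coexpr.select_variable_genes(values, 20)) == set(values.index)

    def test_constant_gene_never_beats_variable(self, rng):
        values = frame(rng.normal(size=(10, 8)))
        values.iloc[0] = 3.0
        selected = coexpr.select_variable_genes(values, 9)
        assert values.index[0] not in selected

    def test_matches_brute_force_variance_sort(self, rng):
        values = frame(rng.normal(size=(30, 12)))
        selected = coexpr.select_variable_genes(values, 10)
        var = values.var(axis=1)
        brute = sorted(values.index, key=lambda g: (-var[g], g))[:10]
        assert selected == brute


class TestAdjacency:
    def test_identical_genes_fully_adjacent(self, rng):
        x = rng.normal(size=10)
        values = frame(np.vstack([x, x]))
        A = coexpr.adjacency(values, beta=6)
        assert A.iloc[0, 1] == pytest.approx(1.0)

    def test_beta_one_is_absolute_correlation(self, rng):
        values = frame(rng.normal(size=(3, 20)))
        A = coexpr.adjacency(values, beta=1)
        corr = np.corrcoef(values.to_numpy())
        np.testing.assert_allclose(A.to_numpy()[np.triu_indices(3, 1)],
                                   np.abs(corr)[np.triu_indices(3, 1)], atol=1e-12)

    def test_matches_brute_force_pairwise_loop(self, rng):
        values = frame(rng.normal(size=(8, 15)))
        A = coexpr.adjacency(values, beta=4).to_numpy()
        arr = values.to_numpy()
        for i in range(8):
            for j in range(i + 1, 8):
                r = np.corrcoef(arr[i], arr[j])[0, 1]
                assert A[i, j] == pytest.approx(abs(r) ** 4, abs=1e-12)

    def test_zero_variance_gene_disconnected(self, rng):
        values = frame(rng.normal(size=(3, 10)))
        values.iloc[0] = 1.0
        A = coexpr.adjacency(values, beta=2)
        assert A.iloc[0, 1] == 0.0 and A.iloc[0, 0] == 1.0


class TestTOM:
    def test_identity_adjacency_gives_zero_overlap(self):
        T = coexpr.tom(pd.DataFrame(np.eye(5)))
        off = T.to_numpy()[np.triu_indices(5, 1)]
        assert np.allclose(off, 0.0)

    def test_hand_example_all_half(self):
        A = pd.DataFrame(np.full((3, 3), 0.5) + np.eye(3) * 0.5)
        T = coexpr.tom(A)
        # (0.25 + 0.5) / (1 + 1 - 0.5) = 0.5
        assert T.iloc[0, 1] == pytest.approx(0.5)

    def test_bounds_on_random_adjacency(self, rng):
        C = np.abs(np.corrcoef(rng.normal(size=(15, 30))))
        np.fill_diagonal(C, 1.0)
        T = coexpr.tom(pd.DataFrame(C ** 3)).to_numpy()
        assert (T >= 0).all() and (T <= 1 + 1e-12).all()
        np.testing.assert_allclose(T, T.T)


def planted_module_matrix(seed, n_genes=600, sizes=(60, 100, 120, 150), r=0.6,
                          n_samples=100):
    rng = np.random.default_rng(seed)
    values = rng.standard_normal((n_genes, n_samples))
    labels = np.array([""] * n_genes, dtype=object)
    start = 0
    for mi, size in enumerate(sizes, 1):
        f = rng.standard_normal(n_samples)
        idx = np.arange(start, start + size)
        values[idx] = np.sqrt(r) * f + np.sqrt(1 - r) * values[idx]
        labels[idx] = f"M{mi}"
        start += size
    return frame(values), pd.Series(labels, index=frame(values).index)


class TestDetectModules:
    def test_block_diagonal_tom_recovers_blocks_exactly(self):
        n, size = 150, 50
        T = np.zeros((n, n))
        for b in range(3):
            T[b * size:(b + 1) * size, b * size:(b + 1) * size] = 0.8
        np.fill_diagonal(T, 1.0)
        ids = [f"g{i:03d}" for i in range(n)]
        labels = coexpr.detect_modules(pd.DataFrame(T, index=ids, columns=ids),
                                       min_size=30)
        assigned = labels[labels != coexpr.UNASSIGNED]
        assert len(assigned) == n
        assert assigned.nunique() == 3
        for b in range(3):
            block = labels.iloc[b * size:(b + 1) * size]
            assert block.nunique() == 1

    def test_noise_tom_mostly_all_grey(self):
        grey_runs = 0
        for s in range(20):
            rng = np.random.default_rng(5000 + s)
            values = frame(rng.normal(size=(100, 30)))
            T = coexpr.tom(coexpr.adjacency(values, beta=6))
            labels = coexpr.detect_modules(T, min_size=30)
            if (labels == coexpr.UNASSIGNED).all():
                grey_runs += 1
        assert grey_runs > 10

    def test_planted_modules_recovered(self):
        values, truth = planted_module_matrix(seed=77)
        T = coexpr.tom(coexpr.adjacency(values, beta=6))
        labels = coexpr.detect_modules(T, min_size=30, matrix=values)
        ari = adjusted_rand_score(truth.to_numpy(), labels.to_numpy())
        assert ari >= 0.8


class TestModuleEigengene:
    def test_identical_profiles_give_unit_kme(self, rng):
        x = rng.normal(size=20)
        values = frame(np.vstack([x, x, x]))
        labels = pd.Series(["M1"] * 3, index=values.index)
        _, kme = coexpr.module_eigengene(values, labels)
        np.testing.assert_allclose(kme["M1"].to_numpy(), 1.0, atol=1e-10)

    def test_unit_norm_and_sign_convention(self, rng):
        values = frame(rng.normal(size=(10, 25)))
        labels = pd.Series(["M1"] * 10, index=values.index)
        eig, _ = coexpr.module_eigengene(values, labels)
        v = eig.loc["M1"].to_numpy()
        assert np.linalg.norm(v) == pytest.approx(1.0)
        assert np.corrcoef(v, values.mean(axis=0))[0, 1] >= 0

    def test_variance_explained_matches_svd_oracle(self, rng):
        values = frame(rng.normal(size=(12, 30)))
        labels = pd.Series(["M1"] * 12, index=values.index)
        eig, _ = coexpr.module_eigengene(values, labels)
        z = values.to_numpy()
        z = (z - z.mean(axis=1, keepdims=True)) / z.std(axis=1, ddof=1, keepdims=True)
        s = np.linalg.svd(z, compute_uv=False)
        projected = z @ eig.loc["M1"].to_numpy()
        assert (projected ** 2).sum() == pytest.approx(s[0] ** 2, rel=1e-8)


class TestMINetworkDPI:
    def test_two_genes_no_triangle(self, rng):
        x = rng.normal(size=50)
        values = frame(np.vstack([x, x + 0.1 * rng.normal(size=50)]))
        edges = coexpr.mi_network_dpi(values, mi_threshold=0.0)
        assert len(edges) == 1
        assert coexpr.mi_network_dpi(values, mi_threshold=1e6).empty

    def test_chain_indirect_edge_pruned(self):
        removed = 0
        n_runs = 20
        for s in range(n_runs):
            rng = np.random.default_rng(9000 + s)
            n = 200
            x = rng.standard_normal(n)
            y = 0.8 * x + np.sqrt(1 - 0.64) * rng.standard_normal(n)
            z = 0.8 * y + np.sqrt(1 - 0.64) * rng.standard_normal(n)
            values = frame(np.vstack([x, y, z]))
            edges = coexpr.mi_network_dpi(values, mi_threshold=0.0)
            pairs = set(map(tuple, edges[["gene_a", "gene_b"]].to_numpy()))
            if ("g000", "g002") not in pairs:
                removed += 1
        assert removed >= int(0.95 * n_runs)

    def test_independent_triple_below_calibrated_threshold(self):
        rng = np.random.default_rng(31)
        values = frame(rng.standard_normal((3, 200)))
        thr = coexpr.mi_permutation_threshold(values, n_perm=200, seed=1)
        edges = coexpr.mi_network_dpi(values, mi_threshold=thr)
        assert len(edges) <= 1  # at the 95th percentile a stray edge is rare

    def test_single_gene_rejected(self, rng):
        with pytest.raises(ValueError):
            coexpr.mi_network_dpi(frame(rng.normal(size=(1, 30))))

    def test_dpi_never_removes_locally_strongest_edge(self, rng):
        values = frame(rng.standard_normal((6, 60)))
        mi = coexpr.pairwise_mi(values)
        edges = coexpr.mi_network_dpi(values, mi_threshold=0.0)
        kept = set(map(tuple, edges[["gene_a", "gene_b"]].to_numpy()))
        ids = list(values.index)
        for a in ids:
            for b in ids:
                if a >= b:
                    continue
                strongest_everywhere = all(
                    mi.loc[a, b] >= min(mi.loc[a, c], mi.loc[b, c])
                    for c in ids
                    if c not in (a, b)
                )
                if strongest_everywhere:
                    assert (a, b) in kept


class TestIdentifyHubs:
    def test_eigengene_like_gene_ranked_first(self, rng):
        f = rng.normal(size=40)
        rows = [f] + [f + 0.8 * rng.normal(size=40) for _ in range(9)]
        values = frame(np.vstack(rows))
        labels = pd.Series(["M1"] * 10, index=values.index)
        _, kme = coexpr.module_eigengene(values, labels)
        hubs = coexpr.identify_hubs(kme, labels, top_k=3)
        assert hubs.hubs["M1"].index[0] == values.index[0]

    def test_identical_condition_networks_no_specific_hubs(self, rng):
        values = frame(rng.normal(size=(12, 40)))
        labels = pd.Series(["M1"] * 12, index=values.index)
        _, kme = coexpr.module_eigengene(values, labels)
        edges = coexpr.mi_network_dpi(values, mi_threshold=0.0)
        hubs = coexpr.identify_hubs(
            kme, labels, top_k=4, mi_edges=edges,
            condition_networks={"case": edges, "control": edges},
        )
        assert not hubs.hubs["M1"]["condition_specific"].any()

    def test_ranking_matches_brute_force_degree_sort(self, rng):
        values = frame(rng.normal(size=(10, 50)))
        labels = pd.Series(["M1"] * 10, index=values.index)
        _, kme = coexpr.module_eigengene(values, labels)
        edges = coexpr.mi_network_dpi(values, mi_threshold=0.0)
        hubs = coexpr.identify_hubs(kme, labels, top_k=10, mi_edges=edges)
        degree = {g: 0.0 for g in values.index}
        for _, row in edges.iterrows():
            degree[row["gene_a"]] += row["mi"]
            degree[row["gene_b"]] += row["mi"]
        brute = sorted(degree, key=lambda g: -degree[g])
        assert list(hubs.hubs["M1"].index) == brute


class TestPickSoftThreshold:
    def test_noise_falls_back_to_six(self, caplog):
        rng = np.random.default_rng(8)
        values = frame(rng.normal(size=(60, 20)))
        arr = values.to_numpy()
        corr = np.abs(np.corrcoef(arr))
        np.fill_diagonal(corr, 0.0)
        none_qualify = all(
            not (r2 >= 0.8 and slope < 0)
            for r2, slope in (coexpr.scale_free_fit((corr ** b).sum(axis=1))
                              for b in range(1, 21))
        )
        beta = coexpr.pick_soft_threshold(values)
        if none_qualify:
            assert beta == 6.0
        else:
            assert 1 <= beta <= 20

    def test_matches_exhaustive_grid_search_oracle(self):
        values, _ = planted_module_matrix(seed=13, n_genes=200, sizes=(50, 60),
                                          n_samples=60)
        beta = coexpr.pick_soft_threshold(values)
        arr = values.to_numpy()
        corr = np.abs(np.corrcoef(arr))
        np.fill_diagonal(corr, 0.0)
        oracle = 6.0
        for b in range(1, 21):
            r2, slope = coexpr.scale_free_fit((corr ** b).sum(axis=1))
            if r2 >= 0.8 and slope < 0:
                oracle = float(b)
                break
        assert beta == oracle
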