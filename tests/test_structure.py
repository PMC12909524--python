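"""Distances, NJ trees, bootstrap, PCA, EM admixture and Evanno Delta-K."""

import numpy as np
import pandas as pd
import pytest

from kaspfp import (
    AdmixtureModel,
    GenotypeMatrix,
    PopulationSimConfig,
    admixture_em,
    allele_sharing_distance,
    bootstrap_support,
    evanno_delta_k,
    genotype_pca,
    nj_tree,
    simulate_population,
)
from kaspfp.errors import ArityError, ConfigurationError, DegenerateInputError
from kaspfp.popstruct.distance import DistanceMatrix


def gm_from(profiles: dict, markers: list) -> GenotypeMatrix:
    return GenotypeMatrix(pd.DataFrame(profiles, index=markers).T)


def random_additive_tree(n, rng):
    """Random binary tree; returns (leaf labels, additive distance matrix)."""
    next_id = [n]
    parents = {}
    lengths = {}
    roots = list(range(n))
    while len(roots) > 1:
        i, j = rng.choice(len(roots), size=2, replace=False)
        a, b = roots[i], roots[j]
        p = next_id[0]
        next_id[0] += 1
        parents[a] = p
        parents[b] = p
        lengths[a] = rng.uniform(0.1, 1.0)
        lengths[b] = rng.uniform(0.1, 1.0)
        roots = [r for r in roots if r not in (a, b)] + [p]
    # leaf-to-leaf path lengths through the rooted tree
    def path_to_root(x):
        out = {}
        d = 0.0
        while x in parents:
            d += lengths[x]
            x = parents[x]
            out[x] = d
        return out

    d = np.zeros((n, n))
    anc = [path_to_root(i) for i in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            common = set(anc[i]) & set(anc[j])
            dij = min(anc[i][c] + anc[j][c] for c in common)
            d[i, j] = d[j, i] = dij
    labels = [f"t{i:02d}" for i in range(n)]
    return labels, d


def patristic(tree):
    """Leaf-to-leaf distances implied by a PhyloTree."""
    adj = {}

    def walk(node):
        for child, bl in node.children:
            adj.setdefault(id(node), []).append((id(child), bl))
            adj.setdefault(id(child), []).append((id(node), bl))
            walk(child)

    walk(tree.root)
    leaves = {}

    def collect(node):
        if node.is_leaf():
            leaves[node.name] = id(node)
        for child, _ in node.children:
            collect(child)

    collect(tree.root)
    out = {}
    for name, start in leaves.items():
        dist = {start: 0.0}
        stack = [start]
        while stack:
            u = stack.pop()
            for v, w in adj.get(u, []):
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for other, nid in leaves.items():
            out[(name, other)] = dist[nid]
    return out


class TestAlleleSharingDistance:
    def test_hand_counted_example(self):
        gm = gm_from(
            {"x": ["AA", "AG", "CC", "GT"], "y": ["AA", "AA", "TT", "GT"]},
            ["m1", "m2", "m3", "m4"],
        )
        dm = allele_sharing_distance(gm)
        assert dm.d[0, 1] == pytest.approx(1 - 5 / 8)

    def test_identical_profiles_have_zero_distance(self):
        gm = gm_from({"x": ["AA", "AG"], "y": ["AA", "AG"]}, ["m1", "m2"])
        assert allele_sharing_distance(gm).d[0, 1] == 0.0

    def test_single_allele_difference_over_31_loci(self):
        prof = ["AA"] * 31
        other = prof.copy()
        other[0] = "AG"
        gm = gm_from({"x": prof, "y": other}, [f"m{i}" for i in range(31)])
        assert allele_sharing_distance(gm).d[0, 1] == pytest.approx(1 - 61 / 62)

    def test_missing_loci_use_pairwise_complete(self):
        gm = gm_from({"x": ["AA", None, "GG"], "y": ["AA", "AG", None]},
                     ["m1", "m2", "m3"])
        dm = allele_sharing_distance(gm)
        assert dm.n_loci_compared[0, 1] == 1
        assert dm.d[0, 1] == 0.0

    def test_semimetric_properties_on_simulation(self, pop30):
        gm, _ = pop30
        dm = allele_sharing_distance(gm)
        assert np.allclose(dm.d, dm.d.T)
        assert np.allclose(np.diag(dm.d), 0.0)
        assert np.nanmin(dm.d) >= 0.0 and np.nanmax(dm.d) <= 1.0


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(
            labels=["A", "B", "C"],
            d=np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float),
            n_loci_compared=np.ones((3, 3), int),
        )
        tree = nj_tree(dm)
        lengths = {c.name: bl for c, bl in tree.root.children}
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})

    def test_additive_five_taxon_recovery(self):
        rng = np.random.default_rng(0)
        labels, d = random_additive_tree(5, rng)
        tree = nj_tree(DistanceMatrix(labels, d, np.ones_like(d, dtype=int)))
        pat = patristic(tree)
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                assert pat[(a, b)] == pytest.approx(d[i, j], abs=1e-9)

    def test_star_topology_yields_zero_internal_branch(self):
        d = np.ones((4, 4)) - np.eye(4)
        tree = nj_tree(DistanceMatrix(list("ABCD"), d, np.ones((4, 4), int)))
        pat = patristic(tree)
        # every leaf pair at distance 1 means the internal edge has length 0
        assert pat[("A", "C")] == pytest.approx(1.0)

    def test_undefined_distance_reported(self):
        d = np.array([[0, np.nan, 1], [np.nan, 0, 1], [1, 1, 0.0]])
        with pytest.raises(ValueError, match="undefined"):
            nj_tree(DistanceMatrix(list("ABC"), d, np.ones((3, 3), int)))

    def test_matches_reference_nj_on_noisy_matrices(self):
        """Topology agrees with scikit-bio's NJ away from ties."""
        import skbio

        rng = np.random.default_rng(5)
        for _ in range(5):
            labels, d = random_additive_tree(7, rng)
            noisy = d + rng.uniform(0, 0.01, size=d.shape)
            noisy = (noisy + noisy.T) / 2
            np.fill_diagonal(noisy, 0.0)
            mine = nj_tree(DistanceMatrix(labels, noisy, np.ones_like(d, dtype=int)))
            ref = skbio.tree.nj(skbio.DistanceMatrix(noisy, labels))
            full = frozenset(labels)
            ref_bips = set()
            for node in ref.non_tips(include_self=False):
                side = frozenset(t.name for t in node.tips())
                if 1 < len(side) < len(labels) - 1:
                    small = side if len(side) <= len(full - side) else full - side
                    if 2 * len(small) == len(full) and min(small) > min(full - small):
                        small = full - small
                    ref_bips.add(small)
            assert mine.bipartitions() == ref_bips


class TestBootstrap:
    def test_single_replicate_supports_are_binary(self, pop30):
        gm, _ = pop30
        tree = bootstrap_support(gm, B=1, seed=0)
        assert set(tree.supports.values()) <= {0.0, 100.0}

    def test_fixed_seed_reproducible(self, pop30):
        gm, _ = pop30
        a = bootstrap_support(gm, B=20, seed=7)
        b = bootstrap_support(gm, B=20, seed=7)
        assert a.supports == b.supports

    def test_strong_differentiation_gets_high_support(self):
        gm, truth = simulate_population(
            PopulationSimConfig(n_accessions=12, n_markers=150, n_subpops=2,
                                fst=0.4, dirichlet_alpha=0.05, missing_rate=0.0, seed=21)
        )
        groups = truth.dominant_ancestry()
        side = frozenset(a for a, g in zip(gm.accessions, groups) if g == groups[0])
        full = frozenset(gm.accessions)
        small = side if len(side) <= len(full - side) else full - side
        if 2 * len(small) == len(full) and min(small) > min(full - small):
            small = full - small
        tree = bootstrap_support(gm, B=100, seed=3)
        assert small in tree.supports
        assert tree.supports[small] >= 95.0

    def test_bootstrap_arity(self, pop30):
        gm, _ = pop30
        with pytest.raises(ArityError):
            bootstrap_support(gm, B=0, seed=0)


class TestGenotypePca:
    def test_duplicated_accessions_coincide(self):
        gm = gm_from(
            {"a": ["AA", "AG", "GG"], "b": ["AA", "AG", "GG"], "c": ["GG", "AA", "AA"]},
            ["m1", "m2", "m3"],
        )
        coords, _ = genotype_pca(gm, 2)
        np.testing.assert_allclose(coords.loc["a"], coords.loc["b"], atol=1e-12)

    def test_variance_fractions_spectral_properties(self, pop30):
        gm, _ = pop30
        _, var = genotype_pca(gm, 5)
        assert np.all(np.diff(var) <= 1e-12)
        assert var.sum() <= 1.0 + 1e-9

    def test_marker_reordering_changes_nothing_up_to_sign(self, pop30):
        gm, _ = pop30
        coords_a, _ = genotype_pca(gm, 2)
        reordered = GenotypeMatrix(gm.df[list(reversed(gm.markers))])
        coords_b, _ = genotype_pca(reordered, 2)
        for pc in coords_a.columns:
            diff = np.abs(coords_a[pc].to_numpy()) - np.abs(coords_b[pc].to_numpy())
            assert np.allclose(diff, 0.0, atol=1e-8)

    def test_constant_matrix_degenerate(self):
        gm = gm_from({"a": ["AA", "AA"], "b": ["AA", "AA"]}, ["m1", "m2"])
        with pytest.raises(DegenerateInputError):
            genotype_pca(gm, 2)

    def test_two_principal_components_recover_ancestry_groups(self):
        gm, truth = simulate_population(
            PopulationSimConfig(n_accessions=105, n_markers=200, n_subpops=3,
                                fst=0.25, dirichlet_alpha=0.1, seed=5)
        )
        from scipy.optimize import linear_sum_assignment
        from sklearn.cluster import KMeans

        coords, _ = genotype_pca(gm, 2)
        labels = KMeans(3, n_init=10, random_state=0).fit_predict(coords.to_numpy())
        true = truth.dominant_ancestry()
        C = np.zeros((3, 3), int)
        for a, b in zip(labels, true):
            C[a, b] += 1
        r, c = linear_sum_assignment(-C)
        assert C[r, c].sum() / len(true) >= 0.90


class TestAdmixtureEM:
    def test_k1_reduces_to_observed_frequencies(self, pop30):
        gm, _ = pop30
        res = admixture_em(gm, K=1, seed=0, n_restarts=1, max_iter=200)
        assert np.allclose(res.Q, 1.0)
        dos = gm.dosage()
        obs = np.nanmean(dos, axis=0) / 2.0
        np.testing.assert_allclose(res.P[0], obs, atol=1e-4)
        # closed-form binomial log-likelihood at the observed frequencies
        q = np.clip(obs, 1e-6, 1 - 1e-6)
        mask = ~np.isnan(dos)
        g = np.nan_to_num(dos)
        ll = np.sum((g * np.log(q) + (2 - g) * np.log(1 - q))[mask])
        assert res.loglik == pytest.approx(ll, rel=1e-6)

    def test_loglik_trace_monotone(self, pop30):
        gm, _ = pop30
        res = admixture_em(gm, K=3, seed=2, n_restarts=1, max_iter=300)
        assert np.all(np.diff(res.loglik_trace) >= -1e-6)

    def test_larger_k_never_fits_worse(self, pop30):
        gm, _ = pop30
        ll1 = admixture_em(gm, K=1, seed=0, n_restarts=1).loglik
        ll2 = admixture_em(gm, K=2, seed=0, n_restarts=3, max_iter=500).loglik
        assert ll2 >= ll1 - 1e-6

    def test_k_exceeding_n_rejected(self, pop30):
        gm, _ = pop30
        with pytest.raises(ConfigurationError):
            AdmixtureModel(gm, K=31)

    def test_summary_mentions_fit(self, pop30):
        gm, _ = pop30
        res = admixture_em(gm, K=2, seed=0, n_restarts=1, max_iter=100)
        text = res.summary()
        assert "log-likelihood" in text and "K:                 2" in text


class TestEvanno:
    def test_hand_worked_table(self):
        tab = evanno_delta_k(
            {1: [-1000, -1002, -998], 2: [-900, -902, -898],
             3: [-880, -884, -876], 4: [-878, -874, -882]}
        )
        assert tab.table.loc[2, "deltaK"] == pytest.approx(40.0)
        assert tab.table.loc[3, "deltaK"] == pytest.approx(4.5)
        assert tab.best_k == 2

    def test_zero_spread_flagged_undefined(self):
        tab = evanno_delta_k(
            {1: [-1000, -1001], 2: [-900, -900], 3: [-880, -882], 4: [-879, -877]}
        )
        assert np.isnan(tab.table.loc[2, "deltaK"])
        assert not np.isnan(tab.table.loc[3, "deltaK"])

    def test_linear_likelihood_means_no_inflection(self):
        tab = evanno_delta_k(
            {1: [-1001, -999], 2: [-901, -899], 3: [-801, -799], 4: [-701, -699]}
        )
        assert tab.table.loc[2, "deltaK"] == 0.0
        assert tab.table.loc[3, "deltaK"] == 0.0

    def test_input_validation(self):
        with pytest.raises(ValueError):
            evanno_delta_k({1: [-10, -11], 2: [-9, -8]})
        with pytest.raises(ValueError):
            evanno_delta_k({1: [-10, -11], 2: [-9, -8], 4: [-7, -6]})
        with pytest.raises(ValueError):
            evanno_delta_k({1: [-10], 2: [-9], 3: [-8]})

    def test_accepts_long_dataframe(self):
        df = pd.DataFrame(
            {"K": [1, 1, 2, 2, 3, 3], "lnP": [-10.0, -12, -6, -8, -5.5, -7.5]}
        )
        tab = evanno_delta_k(df)
        assert set(tab.table.index) == {1, 2, 3}
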