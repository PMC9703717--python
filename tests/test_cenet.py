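"""Correlation gate, triple-axis assembly, clustering and overlap."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from cewhiten.cenet import (
    CeRNAEdge,
    TripleAxis,
    assemble_triples,
    corr_filter,
    kmeans_stage_clusters,
    network_overlap,
    selective_stage_of_centroid,
    spearman,
)
from cewhiten.synthio import archetype_profiles

STAGES = {f"{st}_{r}": st for st in ("D0", "D15", "D85", "Y2") for r in (1, 2, 3)}
SAMPLES = list(STAGES)


class TestSpearman:
    def test_perfect_anticorrelation(self):
        x = np.arange(12, dtype=float)
        rho, _ = spearman(x, -x)
        assert rho == -1.0

    def test_perfect_correlation_never_passes_filter(self):
        x = np.arange(12, dtype=float)
        rho, p = spearman(x, x)
        assert rho == 1.0
        prof = pd.DataFrame([x], index=["a"], columns=SAMPLES)
        mir = pd.DataFrame([x], index=["m"], columns=SAMPLES)
        assert corr_filter([("a", "m")], prof, mir) == []

    def test_zero_variance_undefined(self):
        with pytest.raises(ValueError, match="variance"):
            spearman(np.ones(12), np.arange(12, dtype=float))

    def test_t_approximation_matches_permutation_oracle(self):
        """p at rho about -0.7, n = 12, vs a 1e5-permutation oracle."""
        rng = np.random.default_rng(2024)
        # craft a pair with rank correlation close to -0.7
        x = np.arange(12, dtype=float)
        y = np.array([9.0, 11, 8, 3, 7, 10, 6, 2, 1, 4, 0, 5])
        rho, p = spearman(x, y)
        assert rho == pytest.approx(-0.699, abs=0.01)
        n_perm = 100_000
        perms = np.argsort(rng.random((n_perm, 12)), axis=1)
        xr = (x - x.mean()) / x.std()
        yr = (y - y.mean()) / y.std()  # distinct values: ranks equal values here
        null = (xr * yr[perms]).mean(axis=1)
        p_perm = (np.abs(null) >= abs(rho) - 1e-12).mean()
        mc_sd = np.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert abs(p - p_perm) < max(5 * mc_sd, 0.35 * max(p, p_perm))


class TestCorrFilter:
    def _profiles(self, rows, ids):
        return pd.DataFrame(rows, index=ids, columns=SAMPLES)

    def test_rho_exactly_threshold_excluded(self):
        # construct a pair whose Spearman rho is exactly -0.6: swap two
        # adjacent ranks repeatedly until rho == -0.6 (n=4 gives rho in
        # steps that include -0.6: use [1,2,3,4] vs [3,4,1,2] -> rho=-0.6)
        x = np.array([1.0, 2, 3, 4])
        y = np.array([3.0, 4, 1, 2])
        rho, _ = spearman(x, y)
        assert rho == pytest.approx(-0.6)
        cols = SAMPLES[:4]
        prof = pd.DataFrame([x], index=["a"], columns=cols)
        mir = pd.DataFrame([y], index=["m"], columns=cols)
        assert corr_filter([("a", "m")], prof, mir) == []

    def test_strong_negative_pair_retained(self):
        x = np.arange(12, dtype=float)
        rng = np.random.default_rng(0)
        y = -x + rng.normal(0, 0.5, 12)
        prof = self._profiles([x], ["a"])
        mir = self._profiles([y], ["m"])
        edges = corr_filter([("a", "m")], prof, mir)
        assert len(edges) == 1
        assert edges[0].rho < -0.6 and edges[0].p < 0.05

    def test_missing_profile_skipped(self):
        prof = self._profiles([np.arange(12.0)], ["a"])
        mir = self._profiles([np.arange(12.0)], ["m"])
        assert corr_filter([("ghost", "m"), ("a", "ghost")], prof, mir) == []

    def test_random_pairs_match_brute_force(self):
        """200 random pairs: output equals independent recomputation."""
        rng = np.random.default_rng(5)
        n = 200
        prof = self._profiles(rng.normal(0, 1, (n, 12)), [f"t{i}" for i in range(n)])
        mir = self._profiles(rng.normal(0, 1, (n, 12)), [f"m{i}" for i in range(n)])
        pairs = [(f"t{i}", f"m{i}") for i in range(n)]
        got = {(e.source_id, e.mirna_id) for e in corr_filter(pairs, prof, mir)}
        from scipy.stats import spearmanr

        expected = set()
        for t, m in pairs:
            rho, p = spearmanr(prof.loc[t], mir.loc[m])
            if rho < -0.6 and p < 0.05:
                expected.add((t, m))
        assert got == expected


class TestAssembleTriples:
    def _edge(self, s, m):
        return CeRNAEdge(s, m, -0.8, 0.001)

    def test_single_shared_mirna_single_axis(self):
        axes = assemble_triples([self._edge("c1", "m1")],
                                [self._edge("g1", "m1")], "circRNA")
        assert axes == [TripleAxis("c1", "m1", "g1", "circRNA")]

    def test_mirna_only_on_cerna_side_no_axes(self):
        assert assemble_triples([self._edge("c1", "m1")],
                                [self._edge("g1", "m2")], "circRNA") == []

    def test_two_by_three_gives_six(self):
        cerna = [self._edge(c, "m1") for c in ("c1", "c2")]
        mrna = [self._edge(g, "m1") for g in ("g1", "g2", "g3")]
        axes = assemble_triples(cerna, mrna, "circRNA")
        assert len(axes) == 6
        assert len({(a.cerna_id, a.mrna_id) for a in axes}) == 6

    def test_count_identity_on_random_bipartite_sets(self):
        """Axis count equals both nested-loop enumeration and the degree
        product identity sum_m deg_ceRNA(m) * deg_mRNA(m)."""
        rng = np.random.default_rng(9)
        mirnas = [f"m{i}" for i in range(30)]
        cerna = [
            self._edge(f"c{rng.integers(40)}", mirnas[rng.integers(30)])
            for _ in range(1000)
        ]
        mrna = [
            self._edge(f"g{rng.integers(60)}", mirnas[rng.integers(30)])
            for _ in range(1000)
        ]
        # deduplicate as a pair set, as corr_filter output would be
        cerna = list({(e.source_id, e.mirna_id): e for e in cerna}.values())
        mrna = list({(e.source_id, e.mirna_id): e for e in mrna}.values())
        axes = assemble_triples(cerna, mrna, "circRNA")
        brute = [
            (e.source_id, e.mirna_id, f.source_id)
            for e in cerna for f in mrna if e.mirna_id == f.mirna_id
        ]
        assert len(axes) == len(brute)
        assert sorted((a.cerna_id, a.mirna_id, a.mrna_id) for a in axes) == sorted(brute)
        deg_c = pd.Series([e.mirna_id for e in cerna]).value_counts()
        deg_g = pd.Series([e.mirna_id for e in mrna]).value_counts()
        identity = sum(int(deg_c.get(m, 0)) * int(deg_g.get(m, 0)) for m in mirnas)
        assert len(axes) == identity


class TestClustering:
    def test_k1_single_cluster(self):
        rng = np.random.default_rng(0)
        prof = pd.DataFrame(rng.normal(10, 1, (5, 12)),
                            index=list("abcde"), columns=SAMPLES)
        assign = kmeans_stage_clusters(prof, STAGES, k=1, seed=0)
        assert set(assign.cluster_of_feature.values()) == {1}

    def test_archetype_recovery_ari_one(self):
        rng = np.random.default_rng(7)
        profiles, labels = archetype_profiles(10, 3, 0.1, rng)
        stages = {c: c.rsplit("_", 1)[0] for c in profiles.columns}
        assign = kmeans_stage_clusters(profiles, stages, k=7, seed=0)
        pred = [assign.cluster_of_feature[f] for f in profiles.index]
        assert adjusted_rand_score(labels.to_numpy(), pred) == 1.0

    def test_same_seed_bit_stable_different_seeds_consistent(self):
        rng = np.random.default_rng(13)
        profiles, _ = archetype_profiles(8, 3, 0.1, rng)
        stages = {c: c.rsplit("_", 1)[0] for c in profiles.columns}
        a1 = kmeans_stage_clusters(profiles, stages, k=7, seed=5)
        a2 = kmeans_stage_clusters(profiles, stages, k=7, seed=5)
        assert a1.cluster_of_feature == a2.cluster_of_feature
        a3 = kmeans_stage_clusters(profiles, stages, k=7, seed=6)
        p1 = [a1.cluster_of_feature[f] for f in profiles.index]
        p3 = [a3.cluster_of_feature[f] for f in profiles.index]
        assert adjusted_rand_score(p1, p3) >= 0.95

    def test_too_few_features_fails(self):
        prof = pd.DataFrame(np.ones((3, 12)), index=list("abc"), columns=SAMPLES)
        with pytest.raises(ValueError):
            kmeans_stage_clusters(prof, STAGES, k=7, seed=0)

    def test_centroid_margin_rule(self):
        assert selective_stage_of_centroid([2.0, -0.7, -0.6, -0.7]) == "D0"
        assert selective_stage_of_centroid([0.5, 0.4, -0.4, -0.5]) == "none"


class TestOverlap:
    def _axes(self, mirnas, cls="circRNA"):
        return [TripleAxis(f"c_{m}", m, f"g_{m}", cls) for m in mirnas]

    def test_partial_overlap_fractions(self):
        rep = network_overlap(self._axes(["a", "b", "c"]), self._axes(["b", "c", "d"]))
        assert rep.shared == {"b", "c"}
        assert rep.fraction_vs_a == pytest.approx(2 / 3)
        assert rep.only_a == {"a"} and rep.only_b == {"d"}

    def test_identical_networks(self):
        axes = self._axes(["x", "y"])
        rep = network_overlap(axes, axes)
        assert rep.fraction_vs_a == rep.fraction_vs_b == 1.0

    def test_disjoint_networks(self):
        rep = network_overlap(self._axes(["a"]), self._axes(["b"]))
        assert rep.fraction_vs_a == 0.0 and rep.only_a == {"a"} and rep.only_b == {"b"}
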