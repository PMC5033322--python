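"""Orthogroups, function matrices, repertoire clustering, tree comparison."""

import itertools

import numpy as np
import pandas as pd
import pytest

from clademark import repertoire
from clademark.repertoire import (
    Dendrogram,
    assign_orthogroups,
    build_function_matrix,
    cluster_repertoire,
    compare_dendrograms,
    function_set_counts,
)
from clademark.simulate import CladeSimConfig, simulate_clade, simulate_function_matrix

AA = "ARNDCQEGHILKMFPSTWYV"


def random_protein(rng, length=70) -> str:
    return "".join(AA[i] for i in rng.integers(0, 20, length))


def mutated(rng, p: str, k: int) -> str:
    p = list(p)
    for i in rng.integers(0, len(p), k):
        p[i] = AA[rng.integers(0, 20)]
    return "".join(p)


class TestOrthogroups:
    def test_identical_proteomes_group_per_gene(self):
        rng = np.random.default_rng(0)
        prots = [(f"g{i}", random_protein(rng)) for i in range(6)]
        proteomes = {s: list(prots) for s in ("x", "y", "z")}
        og = assign_orthogroups(proteomes)
        assert len(og.groups) == 6
        assert all(len(g) == 3 for g in og.groups)
        assert og.ungrouped == []

    def test_unrelated_sets_do_not_cross_group(self):
        rng = np.random.default_rng(1)
        proteomes = {
            "x": [(f"x{i}", random_protein(rng)) for i in range(4)],
            "y": [(f"y{i}", random_protein(rng)) for i in range(4)],
        }
        og = assign_orthogroups(proteomes)
        assert og.groups == []
        assert len(og.ungrouped) == 8

    def test_simulated_orthologs_recovered_exactly(self):
        rng = np.random.default_rng(2)
        base = [(f"g{i}", random_protein(rng, 80)) for i in range(5)]
        proteomes = {}
        for s in ("x", "y", "z"):
            proteomes[s] = [(f"{s}|{g}", mutated(rng, p, 6)) for g, p in base]
        # one species-private family in strain x
        proteomes["x"].append(("x|priv", random_protein(rng, 80)))
        og = assign_orthogroups(proteomes)
        partitions = {frozenset(m for m in grp) for grp in og.groups}
        truth = {
            frozenset((s, f"{s}|{g}") for s in ("x", "y", "z")) for g, _ in base
        }
        assert partitions == truth
        assert og.ungrouped == [("x", "x|priv")]

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        base = [(f"g{i}", random_protein(rng, 60)) for i in range(4)]
        proteomes = {
            s: [(f"{s}|{g}", mutated(rng, p, 4)) for g, p in base]
            for s in ("x", "y", "z")
        }
        og1 = assign_orthogroups(proteomes)
        flipped = {k: proteomes[k] for k in reversed(sorted(proteomes))}
        og2 = assign_orthogroups(flipped)
        part1 = {frozenset(g) for g in og1.groups}
        part2 = {frozenset(g) for g in og2.groups}
        assert part1 == part2


class TestFunctionMatrix:
    def test_matches_simulator_truth_without_noise(self):
        rng = np.random.default_rng(4)
        base = [(f"g{i}", random_protein(rng, 80)) for i in range(6)]
        strains = ["x", "y", "z"]
        proteomes = {
            s: [(f"{s}|{g}", mutated(rng, p, 5)) for g, p in base] for s in strains
        }
        og = assign_orthogroups(proteomes)
        m, prov = build_function_matrix(og, strains)
        assert m.shape == (3, 6)
        assert (m.values == 1).all()
        assert set(prov.values()) == {"orthogroup"}

    def test_ungrouped_without_fallback_becomes_singleton(self):
        rng = np.random.default_rng(5)
        proteomes = {
            "x": [("x|a", random_protein(rng))],
            "y": [("y|b", random_protein(rng))],
        }
        og = assign_orthogroups(proteomes)
        m, prov = build_function_matrix(og, ["x", "y"])
        assert set(prov.values()) == {"singleton"}
        assert (m.sum(axis=0) == 1).all()  # each singleton in one strain
        assert (m.sum(axis=0) > 0).all()  # invariant: no all-zero columns

    def test_fallback_database_names_function(self):
        rng = np.random.default_rng(6)
        prot = random_protein(rng, 80)
        proteomes = {
            "x": [("x|a", prot)],
            "y": [("y|b", random_protein(rng, 80))],
        }
        og = assign_orthogroups(proteomes)
        db = [("DBFUNC1", mutated(rng, prot, 4))]
        m, prov = build_function_matrix(
            og,
            ["x", "y"],
            fallback_db=db,
            proteins={("x", "x|a"): prot, ("y", "y|b"): proteomes["y"][0][1]},
        )
        assert "FB:DBFUNC1" in m.columns
        assert prov["FB:DBFUNC1"] == "best_hit_fallback"


class TestFunctionCounts:
    def test_all_ones_matrix(self):
        m = pd.DataFrame(1, index=list("abc"), columns=[f"f{i}" for i in range(5)])
        counts = function_set_counts(m, {"all": list("abc")})
        assert counts["all"]["core"] == 5
        assert counts["all"]["pan"] == 5

    def test_private_column(self):
        m = pd.DataFrame(
            [[1, 1], [1, 0], [1, 0]], index=list("abc"), columns=["core", "apriv"]
        )
        counts = function_set_counts(m, {"A": ["a"], "rest": ["b", "c"]})
        assert counts["A"]["private"] == 1
        assert counts["rest"]["private"] == 0

    def test_empty_subset_rejected(self):
        m = pd.DataFrame([[1]], index=["a"], columns=["f"])
        with pytest.raises(ValueError, match="empty"):
            function_set_counts(m, {"none": []})

    def test_ecotype_core_loss_and_private_gain(self):
        cfg = CladeSimConfig(
            n_species=3,
            strains_per_species=2,
            ecotype_spec=("sp1_s2", 171, 28),
            seed=0,
        )
        labels = {f"sp{k}_s{j}": f"sp{k}" for k in (1, 2, 3) for j in (1, 2)}
        m = simulate_function_matrix(labels, 200, cfg)
        eco = "sp1_s2"
        species_mates = ["sp1_s1"]
        core_cols = [c for c in m.columns if c.startswith("core_")]
        lost = int(
            ((m.loc[species_mates[0], core_cols] == 1) & (m.loc[eco, core_cols] == 0)).sum()
        )
        assert lost == 171
        counts = function_set_counts(m, {"eco": [eco]})
        assert counts["eco"]["private"] == 28


class TestClusterRepertoire:
    def test_hand_upgma_first_merge(self):
        m = pd.DataFrame(
            [[0, 0, 0], [0, 0, 1], [1, 1, 1]],
            index=["s1", "s2", "s3"],
            columns=["f1", "f2", "f3"],
        )
        dend = cluster_repertoire(m, n_boot=0, seed=0)
        Z = dend.linkage_matrix
        # d(s1,s2)=1, d(s1,s3)=3, d(s2,s3)=2 -> first merge {s1,s2} at height 1
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}
        assert Z[0, 2] == pytest.approx(1.0)
        # second merge joins s3 at average distance (3+2)/2
        assert Z[1, 2] == pytest.approx(2.5)

    def test_identical_rows_merge_at_zero(self):
        m = pd.DataFrame(1, index=list("abc"), columns=["f1", "f2"])
        dend = cluster_repertoire(m, n_boot=0, seed=0)
        assert np.allclose(dend.linkage_matrix[:, 2], 0.0)

    def test_manhattan_equals_hamming_and_matches_bruteforce_upgma(self):
        """scipy-based UPGMA heights equal a brute-force implementation on
        random binary matrices (<= 8 strains)."""
        rng = np.random.default_rng(7)
        m = pd.DataFrame(
            rng.integers(0, 2, size=(8, 20)),
            index=[f"s{i}" for i in range(8)],
            columns=[f"f{i}" for i in range(20)],
        )
        # Manhattan == Hamming count on binary rows
        for a, b in itertools.combinations(range(8), 2):
            manh = np.abs(m.values[a] - m.values[b]).sum()
            hamm = (m.values[a] != m.values[b]).sum()
            assert manh == hamm

        def key(a: frozenset, b: frozenset):
            return tuple(sorted((a, b), key=sorted))

        def brute_upgma(dist: dict, items: list[frozenset]):
            heights = []
            d = dict(dist)
            clusters = list(items)
            while len(clusters) > 1:
                i, j = min(
                    ((i, j) for i in range(len(clusters)) for j in range(i + 1, len(clusters))),
                    key=lambda ij: d[key(clusters[ij[0]], clusters[ij[1]])],
                )
                a, b = clusters[i], clusters[j]
                heights.append(d[key(a, b)])
                merged = a | b
                clusters = [c for c in clusters if c not in (a, b)]
                for c in clusters:
                    val = (
                        d[key(a, c)] * len(a) + d[key(b, c)] * len(b)
                    ) / (len(a) + len(b))
                    d[key(merged, c)] = val
                clusters.append(merged)
            return sorted(heights)

        items = [frozenset([i]) for i in range(8)]
        dist = {}
        for a, b in itertools.combinations(range(8), 2):
            val = float(np.abs(m.values[a] - m.values[b]).sum())
            dist[key(frozenset([a]), frozenset([b]))] = val
        brute = brute_upgma(dist, items)
        dend = cluster_repertoire(m, n_boot=0, seed=0)
        assert np.allclose(sorted(dend.linkage_matrix[:, 2]), brute, atol=1e-9)

    def test_merge_heights_nondecreasing_and_bootstrap_certain(self):
        labels = {f"sp{k}_s{j}": f"sp{k}" for k in (1, 2, 3) for j in (1, 2)}
        cfg = CladeSimConfig(n_species=3, strains_per_species=2, seed=1)
        m = simulate_function_matrix(labels, 80, cfg)
        dend = cluster_repertoire(m, n_boot=100, seed=2)
        heights = dend.linkage_matrix[:, 2]
        assert (np.diff(heights) >= -1e-9).all()
        # noise-free species blocks reappear in every resample
        for sp in ("sp1", "sp2", "sp3"):
            pair = frozenset(s for s in labels if labels[s] == sp)
            assert dend.bootstrap[pair] == pytest.approx(100.0)


class TestCompareDendrograms:
    def two_level_matrix(self, eco=False):
        labels = {f"sp{k}_s{j}": f"sp{k}" for k in (1, 2, 3) for j in (1, 2, 3)}
        cfg = CladeSimConfig(
            n_species=3,
            strains_per_species=3,
            n_accessory_functions_per_species=60,
            ecotype_spec=("sp2_s3", 171, 28) if eco else None,
            seed=3,
        )
        return labels, simulate_function_matrix(labels, 300, cfg)

    def test_identical_dendrograms(self):
        _, m = self.two_level_matrix()
        d1 = cluster_repertoire(m, n_boot=0, seed=0)
        d2 = cluster_repertoire(m, n_boot=0, seed=1)
        cmp_res = compare_dendrograms(d1, d2)
        assert cmp_res.cophenetic_correlation == pytest.approx(1.0)
        assert cmp_res.entanglement == pytest.approx(0.0)
        assert cmp_res.discordant == []

    def test_mirrored_leaf_order_is_topology_invariant(self):
        _, m = self.two_level_matrix()
        d1 = cluster_repertoire(m, n_boot=0, seed=0)
        d2 = cluster_repertoire(m.iloc[::-1], n_boot=0, seed=0)
        cmp_res = compare_dendrograms(d1, d2)
        assert cmp_res.cophenetic_correlation == pytest.approx(1.0)
        assert cmp_res.bakers_gamma == pytest.approx(1.0)

    def test_moved_strain_detected_as_discordant(self):
        labels, m = self.two_level_matrix()
        m2 = m.copy()
        m2.loc["sp1_s3"] = m.loc["sp3_s1"]  # adopt another species' profile
        d1 = cluster_repertoire(m, n_boot=0, seed=0)
        d2 = cluster_repertoire(m2, n_boot=0, seed=0)
        cmp_res = compare_dendrograms(d1, d2)
        assert cmp_res.discordant
        assert cmp_res.discordant[0][0] == "sp1_s3"
        assert cmp_res.cophenetic_correlation < 1.0

    def test_leaf_set_mismatch_rejected(self):
        _, m = self.two_level_matrix()
        d1 = cluster_repertoire(m, n_boot=0, seed=0)
        d2 = cluster_repertoire(m.iloc[:-1], n_boot=0, seed=0)
        with pytest.raises(ValueError, match="leaf sets"):
            compare_dendrograms(d1, d2)

    def test_phylo_vs_functional_concordant_without_ecotype(self):
        """With >= k+1 strains per species, every strain's 3 nearest
        neighbours are its conspecifics in both trees: no discordance."""
        from clademark import mlsa

        cfg = CladeSimConfig(
            n_species=3,
            strains_per_species=4,
            n_core_genes=5,
            gene_length_range=(300, 400),
            within_species_divergence=0.01,
            between_species_divergence=0.08,
            n_accessory_functions_per_species=60,
            filler_length=0,
            seed=13,
        )
        clade = simulate_clade(cfg)
        fams = clade.true_core_geneset()
        sm = mlsa.concatenate_alignments([mlsa.align_family(f) for f in fams])
        tree = mlsa.nj_tree_with_bootstrap(sm, model="p", n_boot=10, seed=0)
        m = simulate_function_matrix(clade.species_labels, 300, cfg)
        dend = cluster_repertoire(m, n_boot=0, seed=0)
        cmp_res = compare_dendrograms(tree, dend)
        assert cmp_res.cophenetic_correlation > 0.99
        assert cmp_res.discordant == []
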