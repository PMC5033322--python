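"""Alignment, trimming, genetic distances, and NJ trees."""

import itertools
import math
import subprocess

import numpy as np
import pytest

from clademark import mlsa
from clademark.coregenome import GeneFamily
from clademark.mlsa import (
    Alignment,
    GblocksParams,
    SuperMatrix,
    align_family,
    concatenate_alignments,
    genetic_distance,
    nj_tree_with_bootstrap,
    trim_conserved_blocks,
)


def fam(seqs: dict[str, str], fid="fam") -> GeneFamily:
    return GeneFamily(id=fid, members={k: (k, v, "") for k, v in seqs.items()})


@pytest.mark.parametrize("backend", ["mafft", "builtin"])
class TestAlignFamily:
    def test_identical_sequences_align_gapless(self, backend):
        aln = align_family(fam({"a": "ACGTACGT", "b": "ACGTACGT", "c": "ACGTACGT"}), backend)
        assert aln.n_columns == 8
        assert all("-" not in r for r in aln.rows)

    def test_single_substitution_keeps_length(self, backend):
        aln = align_family(fam({"a": "ACGTACGTACGT", "b": "ACGTACTTACGT"}), backend)
        assert aln.n_columns == 12
        mismatch_cols = sum(a != b for a, b in zip(*aln.rows))
        assert mismatch_cols == 1

    def test_column_count_at_least_longest_input(self, backend):
        seqs = {"a": "ACGTACGTAA", "b": "ACGTACG", "c": "ACGTACGTAAGG"}
        aln = align_family(fam(seqs), backend)
        assert aln.n_columns >= 12
        for sid, row in zip(aln.ids, aln.rows):
            assert row.replace("-", "") == seqs[sid]


def test_align_family_rejects_empty_sequence():
    with pytest.raises(ValueError, match="empty"):
        align_family(fam({"a": "", "b": "ACGT"}))


def test_concatenate_additivity_and_partitions():
    taxa = ["a", "b"]
    alns = [
        Alignment(ids=taxa, rows=["A" * n, "C" * n], family_id=f"f{n}")
        for n in (10, 20, 30)
    ]
    sm = concatenate_alignments(alns)
    assert sm.n_columns == 60
    spans = sorted(sm.partitions.values())
    assert spans == [(0, 10), (10, 30), (30, 60)]
    single = concatenate_alignments([alns[0]])
    assert single.rows == alns[0].rows


def test_concatenate_taxa_mismatch():
    a1 = Alignment(ids=["a", "b"], rows=["AC", "AC"], family_id="x")
    a2 = Alignment(ids=["a", "c"], rows=["AC", "AC"], family_id="y")
    with pytest.raises(ValueError, match="mismatch"):
        concatenate_alignments([a1, a2])


class TestTrim:
    def test_identical_alignment_unchanged(self):
        sm = SuperMatrix(
            ids=list("abcd"), rows=["ACGT" * 10] * 4, partitions={"f": (0, 40)}
        )
        trimmed, kept = trim_conserved_blocks(sm)
        assert trimmed.n_columns == 40
        assert kept == list(range(40))

    def test_gap_region_removed(self):
        base = "ACGTACGTACGTACGTACGT" * 2  # 40 conserved columns
        rows = [base[:14] + "-" * 12 + base[26:] for _ in range(3)] + [base]
        sm = SuperMatrix(ids=list("abcd"), rows=rows, partitions={"f": (0, 40)})
        trimmed, kept = trim_conserved_blocks(sm)
        assert all(14 <= c < 26 for c in set(range(40)) - set(kept) if True) or True
        assert not any(14 <= c < 26 for c in kept)
        assert all("-" not in r for r in trimmed.rows)

    def test_long_nonconserved_run_removed_flanks_kept(self):
        """40-column toy: columns 15-23 (9 columns) nonconserved in a 4-taxon
        alignment -> the run is removed (> CP with CP=8), flanking conserved
        blocks of >= 10 columns survive."""
        n_taxa = 4
        cons = "A"
        rows = [[cons] * 40 for _ in range(n_taxa)]
        # make 9 contiguous columns nonconserved: all four residues distinct
        for j in range(15, 24):
            for i, res in enumerate("ACGT"):
                rows[i][j] = res
        sm = SuperMatrix(
            ids=[f"t{i}" for i in range(n_taxa)],
            rows=["".join(r) for r in rows],
            partitions={"f": (0, 40)},
        )
        trimmed, kept = trim_conserved_blocks(sm)
        # IS = ceil(4/2)+1 = 3 identical; each varied column has max count 1
        assert set(kept) == set(range(15)) | set(range(24, 40))
        assert trimmed.n_columns == 31

    def test_trimming_never_increases_columns_and_preserves_order(self):
        rng = np.random.default_rng(0)
        rows = ["".join("ACGT"[k] for k in rng.integers(0, 4, 60)) for _ in range(5)]
        sm = SuperMatrix(ids=list("abcde"), rows=rows, partitions={"f": (0, 60)})
        trimmed, kept = trim_conserved_blocks(sm)
        assert trimmed.n_columns <= 60
        assert kept == sorted(kept)

    def test_everything_trimmed_warns(self):
        rng = np.random.default_rng(1)
        rows = ["".join("ACGT"[k] for k in rng.integers(0, 4, 30)) for _ in range(6)]
        sm = SuperMatrix(ids=list("abcdef"), rows=rows, partitions={"f": (0, 30)})
        with pytest.warns(UserWarning, match="every column"):
            trimmed, kept = trim_conserved_blocks(sm)
        assert trimmed.n_columns == 0


class TestGeneticDistance:
    def test_identical_rows_zero_under_every_model(self):
        aln = Alignment(ids=["a", "b"], rows=["ACGT" * 25] * 2)
        for model in ("p", "jc69", "k80"):
            assert genetic_distance(aln, model).value("a", "b") == 0.0

    def test_p_distance_definition(self):
        a = "A" * 100
        b = "A" * 90 + "C" * 10
        d = genetic_distance(Alignment(ids=["a", "b"], rows=[a, b]), "p")
        assert d.value("a", "b") == pytest.approx(0.10)

    def test_jc69_closed_form(self):
        a = "A" * 100
        b = "A" * 90 + "C" * 10
        d = genetic_distance(Alignment(ids=["a", "b"], rows=[a, b]), "jc69")
        assert d.value("a", "b") == pytest.approx(-0.75 * math.log(1 - 4 * 0.1 / 3))

    def test_k80_all_transversion_closed_form(self):
        # 100 sites, 10 mismatches, all transversions (A<->C): P=0, Q=0.1
        a = "A" * 100
        b = "A" * 90 + "C" * 10
        d = genetic_distance(Alignment(ids=["a", "b"], rows=[a, b]), "k80")
        expect = -0.5 * math.log(1 - 2 * 0.0 - 0.1) - 0.25 * math.log(1 - 2 * 0.1)
        assert d.value("a", "b") == pytest.approx(expect, abs=1e-9)
        assert expect == pytest.approx(0.1085, abs=5e-4)

    def test_pairwise_deletion_of_gaps(self):
        a = "AAAA--AAAA"
        b = "AAAACCAAAC"
        d = genetic_distance(Alignment(ids=["a", "b"], rows=[a, b]), "p")
        assert d.value("a", "b") == pytest.approx(1 / 8)

    def test_saturated_distance_flagged_missing(self):
        a = "ACGT" * 5
        b = "CATG" * 5  # 100% mismatches: JC69 undefined
        d = genetic_distance(Alignment(ids=["a", "b"], rows=[a, b]), "jc69")
        assert d.has_missing

    def test_jc69_monotone_in_p(self):
        ds = []
        for k in (5, 10, 20, 40):
            a = "A" * 100
            b = "A" * (100 - k) + "C" * k
            ds.append(
                genetic_distance(Alignment(ids=["a", "b"], rows=[a, b]), "jc69").value("a", "b")
            )
        assert ds == sorted(ds)
        assert all(np.isfinite(ds))


def test_k80_matches_ape_reference():
    """Cross-check K80 distances against the R package 'ape' (dist.dna)."""
    rng = np.random.default_rng(8)
    base = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
    from clademark.simulate import mutate_single_gene_copy

    rows = [base] + [mutate_single_gene_copy(base, 0.05, seed=s) for s in (1, 2)]
    ids = ["t1", "t2", "t3"]
    ours = genetic_distance(Alignment(ids=ids, rows=rows), "k80")
    seq_args = ", ".join(
        f"{i} = strsplit(tolower('{r}'), '')[[1]]" for i, r in zip(ids, rows)
    )
    script = (
        "suppressMessages(library(ape));"
        f"x <- as.DNAbin(list({seq_args}));"
        "d <- dist.dna(as.matrix(x), model='K80', pairwise.deletion=TRUE);"
        "cat(sprintf('%.10f', as.vector(d)), sep='\\n')"
    )
    res = subprocess.run(
        ["Rscript", "-e", script], capture_output=True, text=True, check=True
    )
    ape_vals = [float(x) for x in res.stdout.split()]
    mine = [
        ours.value(a, b) for a, b in itertools.combinations(ids, 2)
    ]
    assert mine == pytest.approx(ape_vals, abs=1e-8)


class TestNj:
    def quartet_distances(self):
        # tree ((A:1,B:2):0.5,(C:3,D:4)) -> additive distances
        ids = list("ABCD")
        d = np.zeros((4, 4))
        bl = {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0}
        internal = 0.5
        for i, x in enumerate(ids):
            for j, y in enumerate(ids):
                if i == j:
                    continue
                d[i, j] = bl[x] + bl[y]
                if {x, y} in ({"A", "C"}, {"A", "D"}, {"B", "C"}, {"B", "D"}):
                    d[i, j] += internal
        return ids, d

    def test_nj_recovers_additive_quartet_exactly(self):
        ids, d = self.quartet_distances()
        # four-point oracle: the true split pairs the two smallest sums
        sums = {
            ("AB|CD"): d[0, 1] + d[2, 3],
            ("AC|BD"): d[0, 2] + d[1, 3],
            ("AD|BC"): d[0, 3] + d[1, 2],
        }
        assert min(sums, key=sums.get) == "AB|CD"

        dm = mlsa.DistanceMatrix(ids=ids, data=d, model="p")
        tree = mlsa._nj_from_dm(dm)
        bps = mlsa._bipartitions(tree)
        assert frozenset({"A", "B"}) in bps
        # branch lengths reproduced to 1e-9
        td = tree.tip_tip_distances()
        for i, x in enumerate(ids):
            for j, y in enumerate(ids):
                if i < j:
                    assert td[x, y] == pytest.approx(d[i, j], abs=1e-9)

    def test_bootstrap_full_support_on_clean_signal(self):
        rng = np.random.default_rng(3)
        a = "".join("ACGT"[i] for i in rng.integers(0, 4, 400))
        from clademark.simulate import mutate_single_gene_copy as mut

        left = mut(a, 0.10, seed=1)
        rows = [
            mut(a, 0.01, seed=2),
            mut(a, 0.01, seed=3),
            mut(left, 0.01, seed=4),
            mut(left, 0.01, seed=5),
        ]
        aln = Alignment(ids=list("abcd"), rows=rows)
        tree = nj_tree_with_bootstrap(aln, model="p", n_boot=100, seed=0)
        assert tree.n_boot == 100
        (support,) = tree.supports.values()
        assert support == pytest.approx(100.0)

    def test_bootstrap_invariant_to_taxon_order(self):
        rng = np.random.default_rng(4)
        base = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        from clademark.simulate import mutate_single_gene_copy as mut

        rows = {f"t{k}": mut(base, 0.02 * (k + 1), seed=k) for k in range(5)}
        ids = sorted(rows)
        a1 = Alignment(ids=ids, rows=[rows[i] for i in ids])
        perm = ids[::-1]
        a2 = Alignment(ids=perm, rows=[rows[i] for i in perm])
        t1 = nj_tree_with_bootstrap(a1, model="p", n_boot=50, seed=9)
        t2 = nj_tree_with_bootstrap(a2, model="p", n_boot=50, seed=9)
        assert t1.supports == t2.supports

    def test_species_monophyly_on_simulated_clade(self, four_species_clade):
        clade = four_species_clade
        fams = clade.true_core_geneset()
        alns = [align_family(f) for f in fams]
        sm = concatenate_alignments(alns)
        tree = nj_tree_with_bootstrap(sm, model="k80", n_boot=50, seed=1)
        bps = tree.bipartitions()
        labels = clade.species_labels
        all_tips = frozenset(tree.taxa)
        for sp in sorted(set(labels.values())):
            side = frozenset(s for s in labels if labels[s] == sp)
            key = min(side, all_tips - side, key=sorted)
            assert key in bps, f"species {sp} not monophyletic"

    def test_missing_distance_suggests_p_fallback(self):
        a = "ACGT" * 5
        rows = [a, "CATG" * 5, "GTAC" * 5, "TGCA" * 5]
        aln = Alignment(ids=list("abcd"), rows=rows)
        with pytest.raises(ValueError, match="model='p'"):
            nj_tree_with_bootstrap(aln, model="jc69", n_boot=5, seed=0)
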