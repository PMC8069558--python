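import numpy as np
import pytest
from skbio import DistanceMatrix
from skbio.tree import nj as skbio_nj

from dromtrad.features import SeqRecord
from dromtrad.phylo import (
    Alignment,
    _bipartitions,
    bootstrap_support,
    check_monophyly,
    nj_tree,
    p_distance_matrix,
    tree_from_newick,
    tree_to_newick,
    trivial_alignment,
)
from oracles import random_additive_matrix


class TestPDistance:
    def test_quarter_difference(self):
        _, d = p_distance_matrix(Alignment(["a", "b"], ["ACGT", "ACGA"]))
        assert d[0, 1] == 0.25

    def test_pairwise_deletion(self):
        _, d = p_distance_matrix(Alignment(["a", "b"], ["AC-T", "ACGT"]))
        assert d[0, 1] == 0.0  # 3 compared sites, 0 differences

    def test_ambiguous_sites_removed(self):
        _, d = p_distance_matrix(Alignment(["a", "b"], ["ACNT", "ACGA"]))
        assert d[0, 1] == pytest.approx(1 / 3)

    def test_no_comparable_sites_is_an_error(self):
        with pytest.raises(ValueError, match="no comparable"):
            p_distance_matrix(Alignment(["a", "b"], ["A---", "-CGT"]))

    def test_matches_site_loop_oracle(self):
        rng = np.random.default_rng(8)
        chars = np.array(list("ACGT-N"))
        seqs = ["".join(chars[rng.integers(0, 6, size=500)]) for _ in range(20)]
        labels = [f"s{i}" for i in range(20)]
        _, d = p_distance_matrix(Alignment(labels, seqs))
        for i in range(20):
            for j in range(i + 1, 20):
                comp = diff = 0
                for x, y in zip(seqs[i], seqs[j]):
                    if x in "ACGT" and y in "ACGT":
                        comp += 1
                        diff += x != y
                assert d[i, j] == pytest.approx(diff / comp)
        assert np.all(d >= 0) and np.all(d <= 1) and np.allclose(d, d.T)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 3.0, 4.0], [3.0, 0, 5.0], [4.0, 5.0, 0]])
        tree = nj_tree(["a", "b", "c"], d)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["a"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["b"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["c"] == pytest.approx((4 + 5 - 3) / 2)
        assert tree.total_branch_length_ == pytest.approx(sum(lengths.values()))

    def test_four_taxon_additive_recovery(self):
        # hand-built tree: ((a:1,b:2):1,(c:3,d:4)) as an unrooted quartet
        d = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            dtype=float,
        )
        tree = nj_tree(["a", "b", "c", "d"], d)
        assert _bipartitions(tree) == {frozenset({"a", "b"})}
        # path lengths reproduce the input distances exactly
        tips = {t.name: t for t in tree.tips()}
        for i, x in enumerate("abcd"):
            for j, y in enumerate("abcd"):
                if i < j:
                    assert tips[x].distance(tips[y]) == pytest.approx(d[i, j])

    def test_additive_recovery_matches_skbio(self):
        rng = np.random.default_rng(13)
        for _ in range(25):
            n = int(rng.integers(4, 9))
            d, true_splits = random_additive_matrix(n, rng)
            labels = [f"t{i}" for i in range(n)]
            tree = nj_tree(labels, d)
            assert _bipartitions(tree) == true_splits
            oracle = skbio_nj(DistanceMatrix(d, labels))
            assert _bipartitions(tree) == _bipartitions(oracle)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            nj_tree(["a", "b", "c"], np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]]))

    def test_negative_lengths_clamped(self):
        d = np.array(
            [[0, 0.1, 0.4, 0.35], [0.1, 0, 0.45, 0.4], [0.4, 0.45, 0, 0.05],
             [0.35, 0.4, 0.05, 0]]
        )
        tree = nj_tree(["a", "b", "c", "d"], d)
        assert all(t.length >= 0 for t in tree.traverse(include_self=False))


class TestBootstrap:
    def _clade_alignment(self):
        rng = np.random.default_rng(4)
        base = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=400)])

        def mutate(seq, k, rng):
            out = list(seq)
            for i in rng.choice(len(seq), size=k, replace=False):
                out[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[i]]
            return "".join(out)

        other = mutate(base, 200, rng)  # two highly divergent clades
        seqs = [mutate(base, 8, rng) for _ in range(3)] + [
            mutate(other, 8, rng) for _ in range(3)
        ]
        return Alignment([f"a{i}" for i in range(3)] + [f"b{i}" for i in range(3)], seqs)

    def test_central_split_strongly_supported(self, params):
        aln = self._clade_alignment()
        tree = bootstrap_support(aln, n_reps=100, seed=5, params=params)
        split = frozenset({"a0", "a1", "a2"})
        supports = {
            frozenset(t.name for t in node.tips()): node.name
            for node in tree.non_tips(include_self=False)
        }
        matching = [int(v) for k, v in supports.items()
                    if k in (split, frozenset(aln.labels) - split) and v is not None]
        assert matching and max(matching) >= 95

    def test_same_seed_reproducible(self, params):
        aln = self._clade_alignment()
        t1 = bootstrap_support(aln, n_reps=30, seed=9, params=params)
        t2 = bootstrap_support(aln, n_reps=30, seed=9, params=params)
        assert tree_to_newick(t1) == tree_to_newick(t2)

    def test_identical_sequences_degenerate(self, params):
        aln = Alignment(["a", "b", "c"], ["ACGT" * 10] * 3)
        tree = bootstrap_support(aln, n_reps=10, seed=1, params=params)
        assert tree.degenerate_


class TestMonophyly:
    def test_clade_and_nonclade(self):
        tree = tree_from_newick("((a,b),(c,d));")
        out = check_monophyly(tree, {"g1": {"a", "b"}, "g2": {"a", "c"}})
        assert out == {"g1": True, "g2": False}

    def test_unknown_label_rejected(self):
        tree = tree_from_newick("((a,b),(c,d));")
        with pytest.raises(ValueError, match="unknown"):
            check_monophyly(tree, {"g": {"a", "zzz"}})

    def test_simulated_subgroups_monophyletic(self, params, locus):
        rec, truth = locus
        # functional genes of the three largest subgroups, aligned trivially
        by_sub: dict[str, list[SeqRecord]] = {}
        for g in truth.genes:
            if g.gene_type == "V" and g.functionality == "F":
                by_sub.setdefault(g.subgroup, []).append(
                    SeqRecord(g.label, g.sequence(rec.seq)[-288:])
                )
        chosen = [v for v in by_sub.values() if len(v) >= 2][:3]
        records = [r for grp in chosen for r in grp]
        aln = trivial_alignment(records)
        labels, d = p_distance_matrix(aln)
        tree = nj_tree(labels, d)
        groups = {f"g{i}": {r.id for r in grp} for i, grp in enumerate(chosen)}
        assert all(check_monophyly(tree, groups).values())


class TestNewick:
    def test_round_trip_lengths_and_supports(self, params):
        aln = TestBootstrap()._clade_alignment()
        tree = bootstrap_support(aln, n_reps=20, seed=2, params=params)
        back = tree_from_newick(tree_to_newick(tree))
        assert _bipartitions(back) == _bipartitions(tree)
        orig = {frozenset(t.name for t in n.tips()): (n.name, n.length)
                for n in tree.non_tips(include_self=False)}
        rt = {frozenset(t.name for t in n.tips()): (n.name, n.length)
              for n in back.non_tips(include_self=False)}
        for key, (name, length) in orig.items():
            assert rt[key][0] == name
            assert rt[key][1] == pytest.approx(length, abs=1e-9)
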