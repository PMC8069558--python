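import itertools

import numpy as np
import pytest

from dromtrad.features import revcomp
from dromtrad.germline_scan import (
    classify_functionality,
    find_c_gene,
    find_d_genes,
    find_j_genes,
    find_v_genes,
    scan_rs,
)
from dromtrad.params import Params
from dromtrad.synthetic_locus import LocusBlueprint, generate_locus
from oracles import oracle_rs_hits


class TestScanRS:
    def test_exact_consensus_hit(self, params):
        pad = "TTTT" * 5
        text = pad + "CACAGTG" + "A" * 23 + "ACAAAAACC" + pad
        hits = [h for h in scan_rs(text, 23, params, strand="+") if h.spacer_slack == 0]
        assert len(hits) == 1
        h = hits[0]
        assert h.heptamer_mismatches == 0 and h.nonamer_mismatches == 0
        assert h.heptamer_span == (20, 27)
        assert not h.non_canonical_cac

    def test_noncanonical_heptamer_flagged(self, params):
        # third heptamer base C->T, as on the 9-nt D gene's 3' signal
        text = "G" * 20 + "CATAGTG" + "C" * 23 + "ACAAAAACC" + "G" * 20
        hits = scan_rs(text, 23, params, strand="+")
        assert any(h.heptamer_mismatches == 1 and h.non_canonical_cac for h in hits)

    @pytest.mark.parametrize("max_h, max_n", [(0, 0), (1, 1), (2, 3)])
    def test_matches_sliding_window_oracle(self, max_h, max_n):
        p = Params(max_heptamer_mismatches=max_h, max_nonamer_mismatches=max_n)
        rng = np.random.default_rng(17)
        text = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=3000)])
        text = text[:500] + "CACAGTG" + "T" * 12 + "ACAAAAACC" + text[500:]
        got = {(h.heptamer_span[0], h.strand) for h in scan_rs(text, 12, p)}
        want = oracle_rs_hits(
            text, p.heptamer_consensus, p.nonamer_consensus, 12, max_h, max_n
        )
        assert got == want


class TestFunctionalityRules:
    def test_precedence_over_all_defect_subsets(self):
        kinds = [
            "stop_codon", "frameshift", "missing_leader", "bad_splice_donor",
            "bad_splice_acceptor", "defective_rs", "bad_length", "missing_conserved_aa",
        ]
        pseudo = {"stop_codon", "frameshift"}
        for r in range(len(kinds) + 1):
            for subset in itertools.combinations(kinds, r):
                call = classify_functionality(list(subset))
                if set(subset) & pseudo:
                    assert call == "P"
                elif subset:
                    assert call == "ORF"
                else:
                    assert call == "F"


class TestLocusRecovery:
    def test_v_genes_spans_and_calls_match_truth(self, params, locus):
        rec, truth = locus
        found = find_v_genes(rec, truth.v_references, params)
        tv = [g for g in truth.genes if g.gene_type == "V"]
        assert len(found) == len(tv)
        by_span = {(f.span, f.strand): f for f in found}
        for g in tv:
            f = by_span[(g.span, g.strand)]
            assert f.functionality == g.functionality
            assert sorted(f.defects) == sorted(g.defects)
            assert f.subgroup == g.subgroup

    def test_d_genes_exact(self, params, locus):
        rec, truth = locus
        found = find_d_genes(rec, params)
        assert [f.span for f in found] == [
            g.span for g in truth.genes if g.gene_type == "D"
        ]
        # every D readable through its three coding phases
        assert all(getattr(f, "open_phases") == 3 for f in found)

    def test_j_genes_exact_and_functional(self, params, locus):
        rec, truth = locus
        found = find_j_genes(rec, params)
        assert [f.span for f in found] == [
            g.span for g in truth.genes if g.gene_type == "J"
        ]
        assert all(f.functionality == "F" for f in found)

    def test_j_motif_defect_yields_orf(self, params, locus):
        rec, truth = locus
        g = next(g for g in truth.genes if g.gene_type == "J")
        text = rec.seq
        # mutate the F/W anchor (21 nt before the donor) F->L: TTT -> CTT
        a = g.span[1] - 21
        assert text[a : a + 3] == "TTT"
        mutated = text[:a] + "CTT" + text[a + 1 + 2 :]
        found = find_j_genes(mutated, params)
        hit = next(f for f in found if f.span == g.span)
        assert hit.functionality == "ORF"
        assert hit.defects == ["missing_conserved_aa"]

    def test_strand_symmetry(self, params, locus):
        rec, truth = locus
        n = len(rec.seq)
        mirror_d = find_d_genes(revcomp(rec.seq), params)
        plain_d = find_d_genes(rec.seq, params)
        assert {( n - f.span[1], n - f.span[0]) for f in mirror_d} == {
            f.span for f in plain_d
        }
        mirror_j = find_j_genes(revcomp(rec.seq), params)
        plain_j = find_j_genes(rec.seq, params)
        assert {(n - f.span[1], n - f.span[0]) for f in mirror_j} == {
            f.span for f in plain_j
        }


class TestCGene:
    def test_exon_spans_and_protein_length(self, params, locus):
        rec, truth = locus
        feature = find_c_gene(rec, truth.c_exons, params)
        tc = next(g for g in truth.genes if g.gene_type == "C")
        assert feature.exon_spans == tc.exon_spans
        # three translated exons of 261 + 45 + 108 nt -> 137 aa + stop
        assert feature.protein_length == (261 + 45 + 108) // 3 - 1 == 137

    def test_broken_acceptor_reported(self, params, locus):
        rec, truth = locus
        tc = next(g for g in truth.genes if g.gene_type == "C")
        ex2_start = tc.exon_spans[1][0]
        text = rec.seq
        mutated = text[: ex2_start - 2] + "AC" + text[ex2_start:]
        feature = find_c_gene(mutated, truth.c_exons, params)
        assert "bad_splice_acceptor" in feature.defects
        assert feature.functionality == "ORF"

    def test_missing_exons_error(self, params):
        rng = np.random.default_rng(0)
        text = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=2000)])
        with pytest.raises(ValueError, match="exon"):
            find_c_gene(text, ["ATG" * 80, "CCA" * 15, "GGA" * 30], params)
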