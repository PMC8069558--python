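import numpy as np
import pytest

from dromtrad.features import revcomp
from dromtrad.germline_scan import find_v_genes, scan_rs
from dromtrad.synthetic_locus import (
    LocusBlueprint,
    RepertoireBlueprint,
    generate_locus,
    generate_repertoire,
)


class TestLocusGeneration:
    def test_d_genes_have_both_rs_flanks_and_stated_lengths(self, params, locus):
        rec, truth = locus
        bp = LocusBlueprint()
        d_genes = [g for g in truth.genes if g.gene_type == "D"]
        assert len(d_genes) == bp.n_d
        for g in d_genes:
            assert g.span[1] - g.span[0] in {9, 11, 13}
            upstream = rec.seq[g.span[0] - 40 : g.span[0]]
            downstream = rec.seq[g.span[1] : g.span[1] + 45]
            # 5' side: inverted 12-spacer signal ends exactly at the D start
            five = [h for h in scan_rs(upstream, 12, params, strand="-")
                    if h.heptamer_span[1] == len(upstream)]
            assert five, f"no 5' D signal for {g.label}"
            # 3' side: 23-spacer signal starts exactly at the D end
            three = [h for h in scan_rs(downstream, 23, params, strand="+")
                     if h.heptamer_span[0] == 0]
            assert three, f"no 3' D signal for {g.label}"

    def test_noncanonical_heptamer_on_the_9nt_d(self, params, locus):
        rec, truth = locus
        nine = next(g for g in truth.genes if g.gene_type == "D"
                    and g.span[1] - g.span[0] == 9)
        heptamer = rec.seq[nine.span[1] : nine.span[1] + 7]
        assert heptamer == "CATAGTG"  # third position C->T

    def test_all_functional_when_pseudogene_fraction_zero(self, params):
        bp = LocusBlueprint(genes_per_subgroup={3: 2}, pseudogene_fraction=0.0,
                            include_inverted_v_after_c=False, seed=5)
        rec, truth = generate_locus(bp, params)
        found = find_v_genes(rec, truth.v_references, params)
        assert len(found) == 6
        assert all(f.functionality == "F" for f in found)

    def test_inverted_v_after_c_is_minus_strand(self, locus):
        _, truth = locus
        c = next(g for g in truth.genes if g.gene_type == "C")
        after = [g for g in truth.genes if g.gene_type == "V" and g.span[0] > c.span[1]]
        assert len(after) == 1 and after[0].strand == "-"

    def test_minus_strand_gene_sequence_is_revcomp(self, locus):
        rec, truth = locus
        g = next(g for g in truth.genes if g.gene_type == "V" and g.strand == "-")
        raw = rec.seq[g.span[0] : g.span[1]]
        assert g.sequence(rec.seq) == revcomp(raw)

    def test_infeasible_blueprint_rejected(self, params):
        with pytest.raises(ValueError):
            generate_locus(LocusBlueprint(n_d=0), params)
        with pytest.raises(ValueError):
            generate_locus(LocusBlueprint(pseudogene_fraction=1.5), params)


class TestRepertoireGeneration:
    def test_truth_tiling(self, clean_cohort):
        clones, truth = clean_cohort
        for clone in clones:
            t = truth.clones[clone.id]
            pos = 0
            for _, a, b in t.segments:
                assert a == pos
                pos = b
            assert pos == len(t.cdr3_nt)
            # pre-mutation junction is embedded verbatim in the clone
            assert t.cdr3_nt in clone.seq

    def test_d_list_respects_genomic_order(self, clean_cohort):
        _, truth = clean_cohort
        order = {lab: i for i, (lab, _) in enumerate(truth.d_refs)}
        for t in truth.clones.values():
            idx = [order[lab] for lab in t.d_labels]
            assert idx == sorted(idx) and len(set(idx)) == len(idx)

    def test_zero_d_distribution(self, params, locus):
        _, truth = locus
        bp = RepertoireBlueprint(n_clones=20, d_count_distribution={0: 1.0},
                                 shm_rate=0.0, seed=3)
        clones, truth = generate_repertoire(truth, bp, params)
        assert all(truth.clones[c.id].d_count == 0 for c in clones)

    def test_identity_case_no_trim_no_insertions(self, params, locus):
        # junction must be an exact germline concatenation
        _, truth = locus
        bp = RepertoireBlueprint(
            n_clones=20, shm_rate=0.0, seed=4, max_v_trim=0, max_d_trim=0,
            max_j_trim=0, n_insertion_mean=0.0, max_n_insertion=0,
            p_insertion_probability=0.0,
        )
        clones, truth = generate_repertoire(truth, bp, params)
        d_by_label = dict(truth.d_refs)
        for c in clones:
            t = truth.clones[c.id]
            vref = truth.v_gene_refs[t.v_label]
            jref = next(j for j in truth.j_refs if j.id == t.j_label)
            expected = vref.v_trail + "".join(d_by_label[l] for l in t.d_labels) + jref.head
            assert t.cdr3_nt == expected

    def test_d_count_proportions_match_blueprint(self, params, locus):
        # empirical proportions within 3 binomial SE of 4/14/20/17/6 over 61
        _, truth = locus
        n = 1000
        bp = RepertoireBlueprint(n_clones=n, shm_rate=0.0, seed=9)
        clones, truth = generate_repertoire(truth, bp, params)
        counts = np.zeros(5)
        for c in clones:
            counts[truth.clones[c.id].d_count] += 1
        probs = np.array([4, 14, 20, 17, 6]) / 61
        for k in range(5):
            se = np.sqrt(n * probs[k] * (1 - probs[k]))
            assert abs(counts[k] - n * probs[k]) <= 3 * se

    def test_shm_recorded_and_applied(self, params, locus):
        _, truth = locus
        bp = RepertoireBlueprint(n_clones=30, shm_rate=0.05, seed=6)
        clones, truth = generate_repertoire(truth, bp, params)
        mutated = sum(len(truth.clones[c.id].mutated_positions) for c in clones)
        total = sum(len(c.seq) for c in clones)
        assert 0.03 < mutated / total < 0.07

    def test_empty_reference_sets_rejected(self, params, locus):
        from dataclasses import replace

        _, truth = locus
        import copy

        bare = copy.copy(truth)
        bare.d_refs = []
        with pytest.raises(ValueError):
            generate_repertoire(bare, RepertoireBlueprint(n_clones=1), params)
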