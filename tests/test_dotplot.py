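import numpy as np
import pytest

from dromtrad.dotplot import detect_units, render_dotplot, self_match
from dromtrad.features import revcomp

NT = list("ACGT")


@pytest.fixture(scope="module")
def rng():
    return np.random.default_rng(77)


def _dna(rng, n):
    return "".join(np.array(NT)[rng.integers(0, 4, size=n)])


class TestSelfMatch:
    def test_tandem_duplication_direct(self, rng):
        x = _dna(rng, 2000)
        seq = _dna(rng, 500) + x + x + _dna(rng, 500)
        matches = self_match(seq, word_size=12, min_seg_len=1000, max_gap=50)
        assert len(matches) == 1
        m = matches[0]
        assert m.orientation == "direct"
        assert abs(m.length - 2000) <= 24
        assert abs(m.span_a[0] - 500) <= 12 and abs(m.span_b[0] - 2500) <= 12
        assert m.identity > 99.0

    def test_inverted_duplication(self, rng):
        x = _dna(rng, 2000)
        seq = _dna(rng, 400) + x + _dna(rng, 300) + revcomp(x) + _dna(rng, 400)
        matches = self_match(seq, word_size=12, min_seg_len=1000, max_gap=50)
        assert len(matches) == 1
        m = matches[0]
        assert m.orientation == "inverted"
        assert abs(m.span_a[0] - 400) <= 12 and abs(m.span_b[0] - 2700) <= 12

    def test_canonical_order_and_no_mirrored_duplicates(self, rng):
        x = _dna(rng, 1500)
        seq = x + _dna(rng, 200) + x
        matches = self_match(seq, word_size=12, min_seg_len=1000, max_gap=50)
        assert all(m.span_a[0] < m.span_b[0] for m in matches)
        assert len(matches) == len(set(matches))

    def test_masked_regions_not_seeded(self, rng):
        x = _dna(rng, 1500)
        seq = x + _dna(rng, 200) + x.lower()  # second copy soft-masked
        matches = self_match(seq, word_size=12, min_seg_len=1000, max_gap=50)
        assert matches == []

    def test_revcomp_equivariance(self, rng):
        x = _dna(rng, 1200)
        y = _dna(rng, 1200)
        seq = x + _dna(rng, 300) + y + _dna(rng, 300) + revcomp(x) + y
        n = len(seq)
        fwd = self_match(seq, word_size=12, min_seg_len=900, max_gap=50)
        bwd = self_match(revcomp(seq), word_size=12, min_seg_len=900, max_gap=50)

        def mirror(span):
            return (n - span[1], n - span[0])

        fwd_set = {(m.span_a, m.span_b, m.orientation) for m in fwd}
        bwd_set = set()
        for m in bwd:
            a, b = mirror(m.span_b), mirror(m.span_a)
            if a[0] > b[0]:
                a, b = b, a
            bwd_set.add((a, b, m.orientation))
        assert {o for _, _, o in fwd_set} == {o for _, _, o in bwd_set}
        # mirrored coordinates agree to seed resolution
        for (a, b, o) in fwd_set:
            assert any(
                o == o2 and abs(a[0] - a2[0]) <= 12 and abs(b[0] - b2[0]) <= 12
                for a2, b2, o2 in bwd_set
            )

    def test_word_size_floor(self):
        with pytest.raises(ValueError):
            self_match("ACGT" * 100, word_size=4)


class TestDetectUnits:
    def test_two_disjoint_families(self, rng):
        x, y = _dna(rng, 1500), _dna(rng, 1500)
        seq = x + _dna(rng, 300) + x + _dna(rng, 300) + y + _dna(rng, 300) + y
        matches = self_match(seq, word_size=12, min_seg_len=1000, max_gap=50)
        units = detect_units(matches)
        assert len(units) == 2
        assert all(len(u.member_spans) == 2 for u in units)

    def test_random_sequence_false_positive_control(self, rng):
        seq = _dna(rng, 20000)
        matches = self_match(seq, word_size=12, min_seg_len=1000, max_gap=100)
        units = [u for u in detect_units(matches)
                 if any(b - a >= 1000 for a, b in u.member_spans)]
        assert units == []

    def test_gene_overlay_lists_members_per_span(self, params, locus):
        rec, truth = locus
        matches = self_match(rec, word_size=12, min_seg_len=300, max_gap=60)
        units = detect_units(matches, truth.genes)
        assert units, "expected duplication units in the simulated V cluster"
        # the largest unit family should collect members of one subgroup
        big = max(units, key=lambda u: len(u.member_spans))
        named = [lab for labs in big.genes for lab in labs]
        subs = {lab.split("-")[0] for lab in named}
        assert len(big.member_spans) >= 4
        assert len(subs) == 1  # one subgroup per duplication family here

    def test_duplicated_unit_pairs_recovered(self, params, locus):
        import itertools

        rec, truth = locus
        matches = self_match(rec, word_size=12, min_seg_len=300, max_gap=60)
        sg1 = [g for g in truth.genes if g.subgroup == "SG1"]
        recovered = 0
        for a, b in itertools.combinations(sg1, 2):
            recovered += any(
                m.span_a[0] < a.span[1] and a.span[0] < m.span_a[1]
                and m.span_b[0] < b.span[1] and b.span[0] < m.span_b[1]
                for m in matches
            )
        total = len(sg1) * (len(sg1) - 1) // 2
        assert recovered >= 0.75 * total  # divergence may break a few chains


class TestRender:
    def test_line_coordinates(self, rng, tmp_path):
        x = _dna(rng, 1500)
        seq = x + _dna(rng, 200) + revcomp(x)
        matches = self_match(seq, word_size=12, min_seg_len=1000, max_gap=50)
        lines = render_dotplot(matches, tmp_path / "dp.png", seq_len=len(seq))
        assert len(lines) == 1
        (x0, x1), (y0, y1), orientation = lines[0]
        assert orientation == "inverted"
        assert y0 > y1  # orthogonal to the main diagonal
        assert (tmp_path / "dp.png").exists()

    def test_empty_match_list(self, tmp_path):
        lines = render_dotplot([], tmp_path / "blank.png", seq_len=1000)
        assert lines == []
        assert (tmp_path / "blank.png").exists()
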