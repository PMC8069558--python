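"""Detection and structural classification of V, D, J and C genes.

Genes are located by recombination-signal (RS) motifs, splice sites and
homology to germline references, then classified into the three IMGT-style
functionality classes: F (functional), ORF (open reading frame with
structural defects in splice sites, RS or conserved residues) and P
(pseudogene: stop codons and/or frameshifts in the coding region).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from Bio.Align import PairwiseAligner

from .features import GeneFeature, RSMotif, SeqRecord, VReference, revcomp, translate
from .params import Params

__all__ = [
    "scan_rs",
    "find_v_genes",
    "find_d_genes",
    "find_j_genes",
    "find_c_gene",
    "classify_functionality",
    "annotate_locus",
]

log = logging.getLogger(__name__)

# Expected coding-region lengths (rule "d": estimation of the expected length).
V_EXON_LEN_RANGE = (270, 320)
J_LEN_RANGE = (40, 70)
D_LEN_RANGE = (6, 20)
SPACER_SLACK = 1

_V_IDENTITY_FLOOR = 0.60
_V_COVERAGE_FLOOR = 0.80
_SEED_K = 14


def _as_text(seq: SeqRecord | str) -> str:
    return seq.seq if isinstance(seq, SeqRecord) else seq


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    return aligner


# ---------------------------------------------------------------------------
# RS scanning


def _mismatch_profile(text: np.ndarray, motif: str) -> np.ndarray:
    """mism[i] = Hamming distance between text[i:i+len(motif)] and motif."""
    n, m = len(text), len(motif)
    if n < m:
        return np.zeros(0, dtype=np.int32)
    out = np.zeros(n - m + 1, dtype=np.int32)
    motif_b = np.frombuffer(motif.encode(), dtype=np.uint8)
    for j in range(m):
        out += text[j : n - m + 1 + j] != motif_b[j]
    return out


def scan_rs(
    seq: SeqRecord | str,
    spacer_len: int,
    params: Params,
    strand: str | None = None,
) -> list[RSMotif]:
    """Find heptamer/spacer/nonamer signals with the configured mismatch budget.

    '+' hits read heptamer..spacer..nonamer left to right; '-' hits are the
    reverse-complement pattern (nonamer-rc..spacer..heptamer-rc) as found on
    the 5' side of D and J genes.  A spacer deviation of +-1 nt is accepted
    and recorded in ``spacer_slack``.  Hits are sorted by position then score.
    """
    text_str = _as_text(seq).upper()
    text = np.frombuffer(text_str.encode(), dtype=np.uint8)
    hept, nona = params.heptamer_consensus, params.nonamer_consensus
    hits: list[RSMotif] = []
    strands = [strand] if strand in ("+", "-") else ["+", "-"]
    for st in strands:
        if st == "+":
            first, second = hept, nona
            first_max, second_max = params.max_heptamer_mismatches, params.max_nonamer_mismatches
        else:
            first, second = revcomp(nona), revcomp(hept)
            first_max, second_max = params.max_nonamer_mismatches, params.max_heptamer_mismatches
        mm1 = _mismatch_profile(text, first)
        mm2 = _mismatch_profile(text, second)
        cand = np.nonzero(mm1 <= first_max)[0]
        for slack in (0, -1, 1):
            gap = spacer_len + slack
            offset = len(first) + gap
            for i in cand:
                j = i + offset
                if j >= len(mm2):
                    continue
                if mm2[j] > second_max:
                    continue
                if st == "+":
                    h_span = (int(i), int(i) + len(hept))
                    n_span = (int(j), int(j) + len(nona))
                    h_mm, n_mm = int(mm1[i]), int(mm2[j])
                    hept_seq = text_str[h_span[0] : h_span[1]]
                else:
                    n_span = (int(i), int(i) + len(nona))
                    h_span = (int(j), int(j) + len(hept))
                    n_mm, h_mm = int(mm1[i]), int(mm2[j])
                    hept_seq = revcomp(text_str[h_span[0] : h_span[1]])
                hits.append(
                    RSMotif(
                        heptamer_span=h_span,
                        spacer_len=spacer_len,
                        nonamer_span=n_span,
                        strand=st,
                        heptamer_mismatches=h_mm,
                        nonamer_mismatches=n_mm,
                        score=2.0 * h_mm + n_mm + abs(slack),
                        non_canonical_cac=not hept_seq.startswith("CAC"),
                        spacer_slack=slack,
                    )
                )
    # a hit found at slack 0 should not be duplicated at slack +-1
    best: dict[tuple, RSMotif] = {}
    for h in hits:
        key = (h.heptamer_span, h.strand)
        if key not in best or h.score < best[key].score:
            best[key] = h
    return sorted(best.values(), key=lambda h: (h.start, h.score))


# ---------------------------------------------------------------------------
# homology candidates


@dataclass
class _Candidate:
    ref_id: str
    score: float
    tstart: int
    tend: int
    blocks: list[tuple[tuple[int, int], tuple[int, int]]]  # (target, query) pairs
    identity: float


def _kmer_index(text: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(0, len(text) - k + 1):
        kmer = text[i : i + k]
        if kmer.islower():
            continue  # soft-masked
        index.setdefault(kmer, []).append(i)
    return index


def _seed_windows(index: dict[str, list[int]], ref: str, k: int,
                  text_len: int) -> list[tuple[int, int]]:
    """Cluster k-mer seed diagonals into candidate windows on the target."""
    diags: list[tuple[int, int]] = []  # (diagonal, tpos)
    for r in range(0, len(ref) - k + 1, 4):
        for t in index.get(ref[r : r + k], ()):
            diags.append((t - r, t))
    if not diags:
        return []
    diags.sort()
    windows: list[tuple[int, int]] = []
    group: list[tuple[int, int]] = [diags[0]]
    for d in diags[1:]:
        if d[0] - group[-1][0] <= 40:
            group.append(d)
        else:
            windows.append((group[0][0], group[-1][0]))
            group = [d]
    windows.append((group[0][0], group[-1][0]))
    spans = []
    for d0, d1 in windows:
        start = max(0, d0 - 30)
        end = min(text_len, d1 + len(ref) + 30)
        if end - start >= k:
            spans.append((start, end))
    return spans


def _align_candidate(
    aligner: PairwiseAligner, text: str, window: tuple[int, int], ref: str, ref_id: str
) -> _Candidate | None:
    sub = text[window[0] : window[1]].upper()
    alns = aligner.align(sub, ref.upper())
    if len(alns) == 0:
        return None
    aln = alns[0]
    tblocks, qblocks = aln.aligned
    matches = 0
    columns = 0
    for (t0, t1), (q0, q1) in zip(tblocks, qblocks):
        seg_t = sub[t0:t1]
        seg_q = ref[q0:q1].upper()
        matches += sum(a == b for a, b in zip(seg_t, seg_q))
        columns += t1 - t0
    if columns == 0:
        return None
    coverage = (qblocks[-1][1] - qblocks[0][0]) / len(ref)
    identity = matches / columns
    if identity < _V_IDENTITY_FLOOR or coverage < _V_COVERAGE_FLOOR:
        return None
    blocks = [
        ((int(t0) + window[0], int(t1) + window[0]), (int(q0), int(q1)))
        for (t0, t1), (q0, q1) in zip(tblocks, qblocks)
    ]
    return _Candidate(
        ref_id=ref_id,
        score=float(aln.score),
        tstart=blocks[0][0][0],
        tend=blocks[-1][0][1],
        blocks=blocks,
        identity=identity,
    )


def _project(blocks: list[tuple[tuple[int, int], tuple[int, int]]], r: int) -> int:
    """Map a reference coordinate to a target coordinate through the alignment."""
    for (t0, t1), (q0, q1) in blocks:
        if q0 <= r < q1:
            return t0 + (r - q0)
    (ft0, _), (fq0, _) = blocks[0]
    if r < fq0:
        return ft0 - (fq0 - r)
    (_, lt1), (_, lq1) = blocks[-1]
    if r >= lq1:
        return lt1 + (r - lq1)
    # inside a gap: snap to the start of the following block
    for (t0, t1), (q0, q1) in blocks:
        if r < q0:
            return t0
    return blocks[-1][0][1]


def _resolve_overlaps(cands: list[_Candidate]) -> list[_Candidate]:
    kept: list[_Candidate] = []
    for c in sorted(cands, key=lambda c: (-c.score, c.tstart)):
        if all(c.tend <= k.tstart or k.tend <= c.tstart for k in kept):
            kept.append(c)
    return sorted(kept, key=lambda c: c.tstart)


# ---------------------------------------------------------------------------
# V genes


def _refine_v(
    text: str, cand: _Candidate, ref: VReference, params: Params
) -> tuple[tuple[int, int], list[str], list[RSMotif]]:
    defects: list[str] = []
    gene_start = _project(cand.blocks, 0)
    donor = _project(cand.blocks, ref.intron_span[0])
    acceptor_end = _project(cand.blocks, ref.intron_span[1])
    exon_end = _project(cand.blocks, len(ref.seq))

    # splice motifs are checked at the projected boundaries; chance GT/AG
    # nearby must not relocate a boundary the homology projection fixes
    if text[donor : donor + 2].upper() != "GT":
        defects.append("bad_splice_donor")
    if text[acceptor_end - 2 : acceptor_end].upper() != "AG":
        defects.append("bad_splice_acceptor")

    # V-RS immediately 3' of the V-EXON
    window = (max(0, exon_end - 10), min(len(text), exon_end + 60))
    rs_hits = [
        h
        for h in scan_rs(text[window[0] : window[1]], params.spacer_lengths["V-RS"],
                         params, strand="+")
        if h.score <= _RS_SCORE_STRICT
    ]
    rs: list[RSMotif] = []
    if rs_hits:
        best = min(rs_hits, key=lambda h: (abs(window[0] + h.heptamer_span[0] - exon_end), h.score))
        exon_end = window[0] + best.heptamer_span[0]
        rs.append(
            RSMotif(
                heptamer_span=(window[0] + best.heptamer_span[0], window[0] + best.heptamer_span[1]),
                spacer_len=best.spacer_len,
                nonamer_span=(window[0] + best.nonamer_span[0], window[0] + best.nonamer_span[1]),
                strand=best.strand,
                heptamer_mismatches=best.heptamer_mismatches,
                nonamer_mismatches=best.nonamer_mismatches,
                score=best.score,
                non_canonical_cac=best.non_canonical_cac,
                spacer_slack=best.spacer_slack,
            )
        )
    else:
        defects.append("defective_rs")
        # without an RS anchor the alignment end may over-extend into
        # intergenic sequence; bound it by the reference exon length
        ref_vexon_len = ref.vexon_span[1] - ref.vexon_span[0]
        exon_end = min(exon_end, acceptor_end + ref_vexon_len)

    if not text[gene_start : gene_start + 3].upper() == "ATG":
        defects.append("missing_leader")

    vexon_len = exon_end - acceptor_end
    if not V_EXON_LEN_RANGE[0] <= vexon_len <= V_EXON_LEN_RANGE[1]:
        defects.append("bad_length")

    coding = (text[gene_start:donor] + text[acceptor_end:exon_end]).upper()
    aa = translate(coding)
    if len(coding) % 3 != 0:
        # out-of-frame coding length; downstream stops are a consequence of
        # the frameshift, not reported separately
        defects.append("frameshift")
    elif "*" in aa:
        defects.append("stop_codon")
    if "frameshift" not in defects and ref.conserved_aa:
        for codon_idx, residue in ref.conserved_aa.items():
            if codon_idx >= len(aa) or aa[codon_idx] != residue:
                defects.append("missing_conserved_aa")
                break
    return (gene_start, exon_end), defects, rs


def find_v_genes(
    seq: SeqRecord | str, v_references: list[VReference], params: Params
) -> list[GeneFeature]:
    """Locate V genes by homology to references on both strands and refine
    their L-PART1 + intron + V-EXON structure from splice-site and RS anchors."""
    if not v_references:
        raise ValueError("at least one reference V is required")
    plus = _as_text(seq)
    aligner = _make_aligner()
    features: list[GeneFeature] = []
    length = len(plus)
    for st, text in (("+", plus), ("-", revcomp(plus))):
        index = _kmer_index(text.upper(), _SEED_K)
        cands: list[_Candidate] = []
        for ref in v_references:
            for window in _seed_windows(index, ref.seq.upper(), _SEED_K, len(text)):
                c = _align_candidate(aligner, text, window, ref.seq, ref.id)
                if c is not None:
                    cands.append(c)
        refs_by_id = {r.id: r for r in v_references}
        for c in _resolve_overlaps(cands):
            ref = refs_by_id[c.ref_id]
            span_local, defects, rs = _refine_v(text, c, ref, params)
            if st == "+":
                span = span_local
            else:
                span = (length - span_local[1], length - span_local[0])
            functionality = classify_functionality(defects)
            features.append(
                GeneFeature(
                    label=f"{c.ref_id}@{span[0]}",
                    gene_type="V",
                    span=span,
                    strand=st,
                    functionality=functionality,
                    defects=defects,
                    rs=rs,
                    subgroup=ref.subgroup,
                )
            )
    features.sort(key=lambda f: f.span)
    for i, f in enumerate(features, start=1):
        f.label = f"V{i}"
    return features


# ---------------------------------------------------------------------------
# D and J genes

# Gene calling demands tighter signals than raw scanning: a candidate RS is
# credible only when its mismatch-weighted score (2*heptamer + nonamer +
# |spacer slack|) stays at or below this bound.  The non-canonical heptamer
# observed at some D 3' signals (third position C->T) scores 2 and passes.
_RS_SCORE_STRICT = 2
# J calling is stricter still: J signals are canonical, and a looser budget
# floods the call set with chance inverted 12-spacer signals
_RS_SCORE_STRICT_J = 1


def _find_d_one_strand(text: str, params: Params) -> list[tuple[int, int, list[RSMotif]]]:
    five = [
        h
        for h in scan_rs(text, params.spacer_lengths["5'D-RS"], params, strand="-")
        if h.score <= _RS_SCORE_STRICT
    ]
    three = [
        h
        for h in scan_rs(text, params.spacer_lengths["3'D-RS"], params, strand="+")
        if h.score <= _RS_SCORE_STRICT
    ]
    out = []
    for h5 in five:
        d_start = h5.heptamer_span[1]
        partners = [
            h3
            for h3 in three
            if D_LEN_RANGE[0] <= h3.heptamer_span[0] - d_start <= D_LEN_RANGE[1]
        ]
        if not partners:
            continue
        h3 = min(partners, key=lambda h: (h.score, h.heptamer_span[0]))
        out.append((d_start, h3.heptamer_span[0], [h5, h3]))
    return out


def find_d_genes(seq: SeqRecord | str, params: Params) -> list[GeneFeature]:
    """D genes: short (6-20 nt) segments flanked by an inverted 12-spacer RS on
    the 5' side and a 23-spacer RS on the 3' side."""
    plus = _as_text(seq)
    length = len(plus)
    features: list[GeneFeature] = []
    for st, text in (("+", plus), ("-", revcomp(plus))):
        for d_start, d_end, rs in _find_d_one_strand(text.upper(), params):
            span = (d_start, d_end) if st == "+" else (length - d_end, length - d_start)
            d_seq = text[d_start:d_end].upper()
            open_phases = sum(
                all(d_seq[i : i + 3] not in {"TAA", "TAG", "TGA"}
                    for i in range(f, len(d_seq) - 2, 3))
                for f in range(3)
            )
            feature = GeneFeature(
                label="D?", gene_type="D", span=span, strand=st,
                functionality="F", rs=rs,
            )
            feature.open_phases = open_phases  # type: ignore[attr-defined]
            features.append(feature)
    features.sort(key=lambda f: f.span)
    # drop strand-mirrored duplicates of the same genomic span
    dedup: list[GeneFeature] = []
    for f in features:
        if dedup and dedup[-1].span == f.span:
            continue
        dedup.append(f)
    for i, f in enumerate(dedup, start=1):
        f.label = f"D{i}"
    return dedup


_FW_CODONS = {"TTT", "TTC", "TGG"}
_GLY_CODONS = {"GGA", "GGC", "GGG", "GGT"}
_STOP_CODONS = {"TAA", "TAG", "TGA"}


def _motif_anchor(region: str, end: int) -> int | None:
    """Find an F/W-G-X-G anchor in frame with the donor at ``end``."""
    for a in range(end - 24, end - 11):
        if a < 0 or (end - a) % 3 != 0:
            continue
        c1, c2, c3, c4 = (region[a + 3 * i : a + 3 * i + 3] for i in range(4))
        if (
            c1 in _FW_CODONS
            and c2 in _GLY_CODONS
            and c3 not in _STOP_CODONS
            and len(c4) == 3
            and c4 in _GLY_CODONS
        ):
            return a
    return None


def find_j_genes(seq: SeqRecord | str, params: Params) -> list[GeneFeature]:
    """J genes: inverted 12-spacer RS, a 40-70 nt coding region holding the
    F/W-G-X-G motif in frame with the 3' GT splice donor.  Candidates whose
    motif is absent are kept with a ``missing_conserved_aa`` defect."""
    plus = _as_text(seq)
    length = len(plus)
    features: list[GeneFeature] = []
    for st, text in (("+", plus.upper()), ("-", revcomp(plus).upper())):
        # a D gene's 5' signal is also an inverted 12-spacer RS: exclude
        # signal hits that open a D (a 23-spacer RS follows within D range)
        d_starts = {d_start for d_start, _, _ in _find_d_one_strand(text, params)}
        for h in scan_rs(text, params.spacer_lengths["J-RS"], params, strand="-"):
            if h.score > _RS_SCORE_STRICT_J:
                continue
            j_start = h.heptamer_span[1]
            if j_start in d_starts:
                continue
            donors = [
                e
                for e in range(j_start + J_LEN_RANGE[0], min(j_start + J_LEN_RANGE[1], len(text) - 1))
                if text[e : e + 2] == "GT"
            ]
            if not donors:
                continue
            chosen = None
            for e in donors:
                a = _motif_anchor(text[j_start:e], e - j_start)
                if a is not None:
                    chosen = (e, a, [])
                    break
            if chosen is None:
                chosen = (donors[0], None, ["missing_conserved_aa"])
            e, a, defects = chosen
            span = (j_start, e) if st == "+" else (length - e, length - j_start)
            features.append(
                GeneFeature(
                    label="J?", gene_type="J", span=span, strand=st,
                    functionality=classify_functionality(defects),
                    defects=defects, rs=[h],
                )
            )
    features.sort(key=lambda f: f.span)
    dedup: list[GeneFeature] = []
    for f in features:
        if dedup and dedup[-1].span == f.span:
            continue
        dedup.append(f)
    for i, f in enumerate(dedup, start=1):
        f.label = f"J{i}"
    return dedup


# ---------------------------------------------------------------------------
# C gene


def find_c_gene(
    seq: SeqRecord | str, c_reference: list[str], params: Params
) -> GeneFeature:
    """Locate a C gene by spliced alignment of its reference exons.

    ``c_reference`` gives the exon sequences 5'->3' (three translated + one
    untranslated).  Exon boundaries are GT..AG constrained; the translated
    protein length (excluding the terminal stop) is attached as
    ``protein_length``.
    """
    if len(c_reference) < 3:
        raise ValueError("C reference must provide at least three exons")
    text = _as_text(seq)
    aligner = _make_aligner()
    index = _kmer_index(text.upper(), _SEED_K)
    exon_spans: list[tuple[int, int]] = []
    defects: list[str] = []
    search_from = 0
    for i, exon in enumerate(c_reference):
        best: _Candidate | None = None
        for window in _seed_windows(index, exon.upper(), _SEED_K, len(text)):
            if window[1] <= search_from:
                continue
            c = _align_candidate(aligner, text, window, exon, f"EX{i + 1}")
            if c is not None and c.tstart >= search_from and (best is None or c.score > best.score):
                best = c
        if best is None:
            if i < 3:
                raise ValueError(f"could not locate C exon {i + 1}")
            break
        start = _project(best.blocks, 0)
        end = _project(best.blocks, len(exon))
        exon_spans.append((start, end))
        search_from = end
        if i < len(c_reference) - 1 and text[end : end + 2].upper() != "GT":
            defects.append("bad_splice_donor")
        if i > 0 and text[start - 2 : start].upper() != "AG":
            defects.append("bad_splice_acceptor")
    coding = "".join(text[a:b] for a, b in exon_spans[:3]).upper()
    aa = translate(coding)
    protein_length = len(aa) - 1 if aa.endswith("*") else len(aa)
    if "*" in aa[:-1]:
        defects.append("stop_codon")
    feature = GeneFeature(
        label="C1", gene_type="C", span=(exon_spans[0][0], exon_spans[-1][1]),
        strand="+", functionality=classify_functionality(defects),
        defects=defects, exon_spans=exon_spans,
    )
    feature.protein_length = protein_length  # type: ignore[attr-defined]
    return feature


# ---------------------------------------------------------------------------
# functionality rules


def classify_functionality(defects: list[str]) -> str:
    """Deterministic F/ORF/P call from a defect list.

    Pseudogene evidence (stop codons, frameshifts) dominates; any other
    structural defect yields ORF; a clean structure is functional.
    """
    if {"stop_codon", "frameshift"} & set(defects):
        return "P"
    if defects:
        return "ORF"
    return "F"


def annotate_locus(
    seq: SeqRecord | str,
    v_references: list[VReference],
    c_reference: list[str] | None,
    params: Params,
) -> list[GeneFeature]:
    """Full annotation: V, D, J and (optionally) C genes, sorted by position."""
    features = (
        find_v_genes(seq, v_references, params)
        + find_d_genes(seq, params)
        + find_j_genes(seq, params)
    )
    if c_reference is not None:
        features.append(find_c_gene(seq, c_reference, params))
    features.sort(key=lambda f: f.span)
    return features
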