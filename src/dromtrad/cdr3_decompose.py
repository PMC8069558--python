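"""CDR3-IMGT junction decomposition with multi-D assignment.

The junction algorithm: locate the conserved anchors (2nd-CYS codon 104 of the
V-REGION and the F/W 118 codon of the J F/W-G-X-G motif) by projecting
germline alignments onto the clone, excise the CDR3-IMGT (codons 105-117),
assign germline D segments as non-overlapping stretches of at least
``min_d_match_len`` consecutive nucleotides matching a germline D (each D used
at most once, labels in genomic order), and label the remaining nucleotides as
palindromic (P, at untrimmed germline ends) or non-templated (N) additions.

D assignment is an exact dynamic program: maximise total matched nucleotides,
tie-break on fewer segments, then leftmost placement, then earliest genomic
D label; label ambiguity surviving the tie-breaks is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Align import PairwiseAligner

from .features import CloneRecord, JReference, VReference, revcomp, translate
from .params import Params

__all__ = [
    "Segment",
    "DSegment",
    "JunctionDecomposition",
    "UnassignedError",
    "assign_v_and_j",
    "extract_cdr3",
    "identify_d_segments",
    "label_pn",
    "decompose_clone",
    "decompose_cohort",
    "flag_unplaced_d",
]


class UnassignedError(ValueError):
    """No germline assignment above the identity floor."""


_V_FLOOR_IDENTITY = 0.50
_V_FLOOR_LEN = 100
_J_FLOOR_IDENTITY = 0.50
_J_FLOOR_LEN = 15


@dataclass(frozen=True)
class DSegment:
    """One germline D stretch inside a junction."""

    label: str
    d_index: int
    span: tuple[int, int]      # within the junction string passed to the DP
    d_span: tuple[int, int]    # within the germline D sequence
    mismatches: int = 0

    @property
    def length(self) -> int:
        return self.span[1] - self.span[0]


@dataclass(frozen=True)
class Segment:
    source: str                # V_trail | P | N | D:<label> | J_head
    span: tuple[int, int]      # within cdr3_nt
    mismatches: int = 0
    d_span: tuple[int, int] | None = None


@dataclass
class JunctionDecomposition:
    clone_id: str
    v_label: str
    j_label: str
    cdr3_nt: str
    cdr3_aa: str
    segments: list[Segment]
    productive: bool
    tissue: str = "other"
    v_identity: float = 100.0
    j_identity: float = 100.0
    ambiguous: bool = False

    def __post_init__(self) -> None:
        pos = 0
        for seg in self.segments:
            if seg.span[0] != pos:
                raise ValueError(
                    f"{self.clone_id}: segments do not tile the junction "
                    f"(gap/overlap at {pos} vs {seg.span})"
                )
            pos = seg.span[1]
        if pos != len(self.cdr3_nt):
            raise ValueError(f"{self.clone_id}: segments do not cover the junction")
        labels = [s.source[2:] for s in self.segments if s.source.startswith("D:")]
        keys = [self._genomic_key(lab) for lab in labels]
        if keys != sorted(keys):
            raise ValueError(f"{self.clone_id}: D labels out of genomic order")

    @staticmethod
    def _genomic_key(label: str):
        # D labels are positional (D1..Dn); sort numerically when possible
        import re

        m = re.fullmatch(r"\D*(\d+)", label)
        return (0, int(m.group(1))) if m else (1, label)

    @property
    def d_count(self) -> int:
        return sum(1 for s in self.segments if s.source.startswith("D:"))

    @property
    def d_labels(self) -> list[str]:
        return [s.source[2:] for s in self.segments if s.source.startswith("D:")]

    @property
    def cdr3_len_aa(self) -> int:
        return len(self.cdr3_nt) // 3

    def segment_string(self) -> str:
        parts = []
        for s in self.segments:
            if s.source.startswith("D:"):
                a, b = s.d_span  # type: ignore[misc]
                parts.append(f"D:{s.source[2:]}[{a + 1}-{b}]")
            elif s.source in ("P", "N"):
                parts.append(f"{s.source}:{s.span[1] - s.span[0]}")
            else:
                parts.append(f"{s.source}:{s.span[1] - s.span[0]}")
        return "|".join(parts)


# ---------------------------------------------------------------------------
# V / J assignment and CDR3 extraction


def _local_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    return aligner


_ALIGNER = _local_aligner()


@dataclass
class _Hit:
    label: str
    score: float
    identity: float
    aligned_len: int
    blocks: list[tuple[tuple[int, int], tuple[int, int]]]  # (clone, ref)


def _best_hit(clone_seq: str, refs: list[tuple[str, str]]) -> _Hit | None:
    best: _Hit | None = None
    for label, ref_seq in sorted(refs):
        alns = _ALIGNER.align(clone_seq.upper(), ref_seq.upper())
        if len(alns) == 0:
            continue
        aln = alns[0]
        tb, qb = aln.aligned
        matches = sum(
            sum(x == y for x, y in zip(clone_seq[t0:t1].upper(), ref_seq[q0:q1].upper()))
            for (t0, t1), (q0, q1) in zip(tb, qb)
        )
        alen = sum(t1 - t0 for t0, t1 in tb)
        hit = _Hit(
            label=label,
            score=float(aln.score),
            identity=matches / alen if alen else 0.0,
            aligned_len=alen,
            blocks=[((int(t0), int(t1)), (int(q0), int(q1))) for (t0, t1), (q0, q1) in zip(tb, qb)],
        )
        if best is None or hit.score > best.score:
            best = hit
    return best


def _project_ref_to_clone(blocks, r: int) -> int:
    for (t0, t1), (q0, q1) in blocks:
        if q0 <= r < q1:
            return t0 + (r - q0)
    (ft0, _), (fq0, _) = blocks[0]
    if r < fq0:
        return ft0 - (fq0 - r)
    (_, lt1), (_, lq1) = blocks[-1]
    return lt1 + (r - lq1)


def assign_v_and_j(
    clone: CloneRecord,
    v_refs: list[VReference],
    j_refs: list[JReference],
    params: Params,
) -> tuple[_Hit, _Hit]:
    """Best-scoring local alignment of the clone against each reference set.

    Mutation-tolerant (local alignment with mismatch penalties) so somatic
    hypermutation does not break assignment; ties broken by reference label
    order; reported identities make the mutation load visible.
    """
    if not v_refs or not j_refs:
        raise ValueError("reference sets must be non-empty")
    v_hit = _best_hit(clone.seq, [(r.id, r.coding_seq) for r in v_refs])
    if v_hit is None or v_hit.identity < _V_FLOOR_IDENTITY or v_hit.aligned_len < _V_FLOOR_LEN:
        raise UnassignedError(f"clone {clone.id}: no V assignment above the floor")
    j_hit = _best_hit(clone.seq, [(r.id, r.seq) for r in j_refs])
    if j_hit is None or j_hit.identity < _J_FLOOR_IDENTITY or j_hit.aligned_len < _J_FLOOR_LEN:
        raise UnassignedError(f"clone {clone.id}: no J assignment above the floor")
    return v_hit, j_hit


def extract_cdr3(
    clone: CloneRecord,
    v_hit: _Hit,
    j_hit: _Hit,
    v_ref: VReference,
    j_ref: JReference,
    params: Params,
) -> tuple[str, str, bool]:
    """Excise the CDR3-IMGT: nucleotides strictly between the codon aligned to
    the V 2nd-CYS (position 104) and the codon aligned to the J anchor (118).

    Anchors are projected through the germline alignments, not searched de
    novo, so mutations at the anchors do not break extraction.  Returns
    (cdr3_nt, cdr3_aa, productive); out-of-frame anchors flag the clone
    non-productive.
    """
    cys_end = _project_ref_to_clone(v_hit.blocks, v_ref.cys2_codon_start + 3)
    anchor = _project_ref_to_clone(j_hit.blocks, j_ref.anchor_offset)
    if not 0 <= cys_end < anchor <= len(clone.seq):
        return "", "", False
    cdr3_nt = clone.seq[cys_end:anchor].upper()
    in_frame = len(cdr3_nt) % 3 == 0
    cdr3_aa = translate(cdr3_nt) if in_frame else ""
    productive = in_frame and "*" not in cdr3_aa and len(cdr3_nt) > 0
    return cdr3_nt, cdr3_aa, productive


# ---------------------------------------------------------------------------
# D segment dynamic programming


def _candidate_segments(
    junction: str, d_refs: list[tuple[str, str]], params: Params
) -> dict[int, list[DSegment]]:
    """All stretches >= min_d_match_len matching a germline D with at most
    max_d_mismatches substitutions, grouped by start position."""
    n = len(junction)
    by_start: dict[int, list[DSegment]] = {}
    for d_index, (label, d_seq) in enumerate(d_refs):
        m = len(d_seq)
        d_up = d_seq.upper()
        for i in range(n - params.min_d_match_len + 1):
            for j in range(m - params.min_d_match_len + 1):
                mism = 0
                max_len = min(n - i, m - j)
                length = 0
                mism_at: list[int] = []
                while length < max_len:
                    if junction[i + length] != d_up[j + length]:
                        mism += 1
                        if mism > params.max_d_mismatches:
                            break
                        mism_at.append(length)
                    length += 1
                for L in range(params.min_d_match_len, length + 1):
                    used_mism = sum(1 for p in mism_at if p < L)
                    # skip candidates whose terminal position is a mismatch:
                    # they are dominated by the shorter exact-ended stretch
                    if L - 1 in mism_at:
                        continue
                    by_start.setdefault(i, []).append(
                        DSegment(
                            label=label,
                            d_index=d_index,
                            span=(i, i + L),
                            d_span=(j, j + L),
                            mismatches=used_mism,
                        )
                    )
    return by_start


def identify_d_segments(
    junction: str, d_refs: list[tuple[str, str]], params: Params
) -> tuple[list[DSegment], bool]:
    """Optimal non-overlapping assignment of germline D stretches.

    ``d_refs`` must be in genomic order.  Selected labels are non-decreasing
    in genomic order, each D used at most once; the objective maximises total
    matched nucleotides, then prefers fewer segments, then leftmost placement,
    then earliest genomic labels.  Returns (segments, ambiguous_flag); zero
    segments is a valid result (direct V-J junction).
    """
    if params.min_d_match_len < 3:
        raise ValueError("min_d_match_len must be >= 3")
    junction = junction.upper()
    n = len(junction)
    by_start = _candidate_segments(junction, d_refs, params)

    from functools import lru_cache

    @lru_cache(maxsize=None)
    def best(i: int, dmin: int) -> tuple[int, int, tuple[DSegment, ...]]:
        """Best (total_matched, -n_segments... ) suffix solution from i with
        D indices >= dmin.  Returns (total, nsegs, segments)."""
        if i >= n:
            return (0, 0, ())
        # option 1: leave position i unassigned
        candidates = [best(i + 1, dmin)]
        for seg in by_start.get(i, ()):  # option 2: take a segment at i
            if seg.d_index < dmin:
                continue
            total, nsegs, rest = best(seg.span[1], seg.d_index + 1)
            candidates.append((total + seg.length, nsegs + 1, (seg,) + rest))
        return min(
            candidates,
            key=lambda c: (
                -c[0],
                c[1],
                tuple(s.span[0] for s in c[2]),
                tuple(s.d_index for s in c[2]),
                tuple(s.d_span[0] for s in c[2]),
            ),
        )

    _, _, chosen = best(0, 0)
    segments = list(chosen)

    # ambiguity: an equally long alternative label for any chosen stretch
    ambiguous = False
    for k, seg in enumerate(segments):
        lo = segments[k - 1].d_index + 1 if k > 0 else 0
        hi = segments[k + 1].d_index - 1 if k + 1 < len(segments) else len(d_refs) - 1
        for alt in by_start.get(seg.span[0], ()):
            if (
                alt.span == seg.span
                and alt.d_index != seg.d_index
                and lo <= alt.d_index <= hi
                and alt.mismatches <= seg.mismatches
            ):
                ambiguous = True
    return segments, ambiguous


# ---------------------------------------------------------------------------
# P/N labelling


def _longest_prefix_match(s: str, t: str) -> int:
    n = 0
    for a, b in zip(s, t):
        if a != b:
            break
        n += 1
    return n


def _p_right(germline: str, k: int) -> str:
    return revcomp(germline[-k:])


def _p_left(germline: str, k: int) -> str:
    return revcomp(germline[:k])


def label_pn(
    cdr3_nt: str,
    v_trail_len: int,
    j_head_start: int,
    d_segments: list[Segment],
    v_ref: VReference,
    d_refs: list[tuple[str, str]],
    j_ref: JReference,
    params: Params,
) -> list[Segment]:
    """Fill the unassigned runs of a junction with P and N labels.

    P: up to ``max_p_len`` nucleotides adjacent to an untrimmed germline end
    that form the reverse complement of that end (palindromic additions).
    Everything else unassigned is N.
    """
    d_by_label = dict(d_refs)
    assigned: list[Segment] = []
    if v_trail_len:
        assigned.append(Segment("V_trail", (0, v_trail_len)))
    assigned.extend(d_segments)
    if j_head_start < len(cdr3_nt):
        assigned.append(Segment("J_head", (j_head_start, len(cdr3_nt))))
    assigned.sort(key=lambda s: s.span)

    def left_p(run: str, left_seg: Segment | None) -> int:
        """Length of P at the start of the run (templated by the left end)."""
        if left_seg is None:
            germ, untrimmed = v_ref.v_trail, v_trail_len == len(v_ref.v_trail)
            if v_trail_len == 0:
                untrimmed = False
        elif left_seg.source == "V_trail":
            germ, untrimmed = v_ref.v_trail, v_trail_len == len(v_ref.v_trail)
        else:
            germ = d_by_label[left_seg.source[2:]]
            untrimmed = left_seg.d_span is not None and left_seg.d_span[1] == len(germ)
        if not untrimmed:
            return 0
        for k in range(min(params.max_p_len, len(run)), 0, -1):
            if run[:k] == _p_right(germ, k):
                return k
        return 0

    def right_p(run: str, right_seg: Segment | None) -> int:
        if right_seg is None or right_seg.source == "J_head":
            germ = j_ref.seq
            untrimmed = j_head_start < len(cdr3_nt) and (
                len(cdr3_nt) - j_head_start == len(j_ref.head)
            )
        else:
            germ = d_by_label[right_seg.source[2:]]
            untrimmed = right_seg.d_span is not None and right_seg.d_span[0] == 0
        if not untrimmed:
            return 0
        for k in range(min(params.max_p_len, len(run)), 0, -1):
            if run[-k:] == _p_left(germ, k):
                return k
        return 0

    out: list[Segment] = []
    pos = 0
    for idx, seg in enumerate(assigned + [None]):  # type: ignore[list-item]
        run_end = seg.span[0] if seg is not None else len(cdr3_nt)
        if run_end > pos:
            run = cdr3_nt[pos:run_end]
            left_seg = assigned[idx - 1] if idx > 0 else None
            lp = left_p(run, left_seg)
            rp = right_p(run[lp:], seg) if len(run) - lp > 0 else 0
            if lp:
                out.append(Segment("P", (pos, pos + lp)))
            if len(run) - lp - rp > 0:
                out.append(Segment("N", (pos + lp, run_end - rp)))
            if rp:
                out.append(Segment("P", (run_end - rp, run_end)))
        if seg is not None:
            out.append(seg)
            pos = seg.span[1]
        else:
            pos = run_end
    return out


# ---------------------------------------------------------------------------
# clone- and cohort-level drivers


def decompose_clone(
    clone: CloneRecord,
    v_refs: list[VReference],
    j_refs: list[JReference],
    d_refs: list[tuple[str, str]],
    params: Params,
) -> JunctionDecomposition:
    """Full junction decomposition of one clone."""
    v_hit, j_hit = assign_v_and_j(clone, v_refs, j_refs, params)
    v_ref = next(r for r in v_refs if r.id == v_hit.label)
    j_ref = next(r for r in j_refs if r.id == j_hit.label)
    cdr3_nt, cdr3_aa, productive = extract_cdr3(clone, v_hit, j_hit, v_ref, j_ref, params)
    if not cdr3_nt:
        return JunctionDecomposition(
            clone_id=clone.id, v_label=v_hit.label, j_label=j_hit.label,
            cdr3_nt="", cdr3_aa="", segments=[], productive=False,
            tissue=clone.tissue.value,
            v_identity=100 * v_hit.identity, j_identity=100 * j_hit.identity,
        )
    trail = v_ref.v_trail.upper()
    head = j_ref.head.upper()
    v_trail_len = _longest_prefix_match(cdr3_nt, trail)
    max_head = min(len(head), len(cdr3_nt) - v_trail_len)
    j_head_len = _longest_prefix_match(cdr3_nt[::-1], head[::-1][:max_head])
    j_head_start = len(cdr3_nt) - j_head_len

    middle = cdr3_nt[v_trail_len:j_head_start]
    d_segs_raw, ambiguous = identify_d_segments(middle, d_refs, params)
    d_segments = [
        Segment(
            source=f"D:{s.label}",
            span=(s.span[0] + v_trail_len, s.span[1] + v_trail_len),
            mismatches=s.mismatches,
            d_span=s.d_span,
        )
        for s in d_segs_raw
    ]
    segments = label_pn(
        cdr3_nt, v_trail_len, j_head_start, d_segments, v_ref, d_refs, j_ref, params
    )
    return JunctionDecomposition(
        clone_id=clone.id, v_label=v_hit.label, j_label=j_hit.label,
        cdr3_nt=cdr3_nt, cdr3_aa=cdr3_aa, segments=segments,
        productive=productive, tissue=clone.tissue.value,
        v_identity=100 * v_hit.identity, j_identity=100 * j_hit.identity,
        ambiguous=ambiguous,
    )


def decompose_cohort(
    clones: list[CloneRecord],
    v_refs: list[VReference],
    j_refs: list[JReference],
    d_refs: list[tuple[str, str]],
    params: Params,
) -> list[JunctionDecomposition]:
    return [decompose_clone(c, v_refs, j_refs, d_refs, params) for c in clones]


def flag_unplaced_d(
    decompositions: list[JunctionDecomposition],
    d_refs: list[tuple[str, str]],
    params: Params,
    min_clones: int = 3,
) -> list[tuple[str, int]]:
    """Report recurrent unassigned motifs: N-labelled substrings of length >=
    min_d_match_len shared exactly by at least ``min_clones`` clones, as
    candidate D genes missing from the germline reference.

    Maximal candidates only: a substring is dropped when a longer candidate
    containing it is shared by the same clones.
    """
    per_clone: list[set[str]] = []
    for dec in decompositions:
        subs: set[str] = set()
        for seg in dec.segments:
            if seg.source != "N":
                continue
            run = dec.cdr3_nt[seg.span[0] : seg.span[1]]
            for L in range(params.min_d_match_len, len(run) + 1):
                for i in range(len(run) - L + 1):
                    subs.add(run[i : i + L])
        per_clone.append(subs)
    counts: dict[str, int] = {}
    for subs in per_clone:
        for s in subs:
            counts[s] = counts.get(s, 0) + 1
    candidates = {s: c for s, c in counts.items() if c >= min_clones}
    maximal = []
    for s, c in candidates.items():
        if any(s != t and s in t and ct >= c for t, ct in candidates.items()):
            continue
        maximal.append((s, c))
    maximal.sort(key=lambda x: (-x[1], -len(x[0]), x[0]))
    return maximal
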