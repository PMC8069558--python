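"""Genomic self-comparison dot-plot and duplication-unit detection.

Internal homology units — tandemly duplicated blocks and inversions — appear
as off-diagonal lines in a self-alignment dot plot: parallel to the main
diagonal for direct repeats, orthogonal for inverted ones.  Matching is exact
k-mer seeding chained along diagonals (anti-diagonals for the reverse
complement), with soft-masked (lowercase) regions skipped at the seeding
stage only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .features import GeneFeature, SeqRecord, revcomp

__all__ = ["MatchSegment", "DuplicationUnit", "self_match", "detect_units", "render_dotplot"]

_MAX_KMER_OCCURRENCES = 100


@dataclass(frozen=True)
class MatchSegment:
    span_a: tuple[int, int]
    span_b: tuple[int, int]
    orientation: str  # direct | inverted
    length: int
    identity: float

    def __post_init__(self) -> None:
        if self.orientation not in ("direct", "inverted"):
            raise ValueError(f"bad orientation {self.orientation!r}")
        if self.span_a[0] > self.span_b[0]:
            raise ValueError("span_a must start before span_b (canonical order)")


@dataclass
class DuplicationUnit:
    member_spans: list[tuple[int, int]]
    orientation_pattern: str  # direct | inverted | mixed
    genes: list[list[str]] = field(default_factory=list)  # per member span


def _as_text(seq: SeqRecord | str) -> str:
    return seq.seq if isinstance(seq, SeqRecord) else seq


def _seed_positions(text: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(text) - k + 1):
        window = text[i : i + k]
        if window != window.upper():
            continue  # soft-masked: skip for seeding
        index.setdefault(window.upper(), []).append(i)
    return index


def _chain(pairs: list[tuple[int, int]], k: int, max_gap: int) -> list[tuple[int, int]]:
    """Chain seed start positions (sorted) into (first, last) runs with gaps
    <= max_gap between consecutive seed starts."""
    runs = []
    start = prev = pairs[0]
    for p in pairs[1:]:
        if p - prev <= max_gap + k:
            prev = p
        else:
            runs.append((start, prev))
            start = prev = p
    runs.append((start, prev))
    return runs


def _identity(a: str, b: str) -> float:
    assert len(a) == len(b)
    if not a:
        return 0.0
    return 100.0 * sum(x == y for x, y in zip(a, b)) / len(a)


def self_match(
    seq: SeqRecord | str,
    word_size: int = 12,
    min_seg_len: int = 1000,
    max_gap: int = 100,
) -> list[MatchSegment]:
    """Find direct and inverted internal homology segments of a sequence
    against itself.  The trivial main diagonal is excluded; output is
    canonical (span_a before span_b) and sorted."""
    if word_size < 8:
        raise ValueError("word_size must be >= 8")
    raw = _as_text(seq)
    text = raw.upper()
    k = word_size
    index = _seed_positions(raw, k)
    segments: list[MatchSegment] = []

    # direct repeats: same-strand k-mer pairs grouped by diagonal j - i
    by_diag: dict[int, list[int]] = {}
    for positions in index.values():
        if len(positions) > _MAX_KMER_OCCURRENCES:
            continue
        for ai in range(len(positions)):
            for bi in range(ai + 1, len(positions)):
                i, j = positions[ai], positions[bi]
                by_diag.setdefault(j - i, []).append(i)
    for diag, starts in by_diag.items():
        if diag == 0:
            continue
        starts.sort()
        for first, last in _chain(starts, k, max_gap):
            length = last + k - first
            if length < min_seg_len:
                continue
            a = (first, first + length)
            b = (first + diag, first + diag + length)
            segments.append(
                MatchSegment(
                    span_a=a, span_b=b, orientation="direct", length=length,
                    identity=_identity(text[a[0] : a[1]], text[b[0] : b[1]]),
                )
            )

    # inverted repeats: k-mer i matching revcomp k-mer at j, anti-diagonal i + j
    rc = revcomp(raw)
    rc_index = _seed_positions(rc, k)
    n = len(raw)
    by_anti: dict[int, list[int]] = {}
    for kmer, positions in index.items():
        rc_hits = rc_index.get(kmer, ())
        if len(positions) > _MAX_KMER_OCCURRENCES or len(rc_hits) > _MAX_KMER_OCCURRENCES:
            continue
        for i in positions:
            for p in rc_hits:
                j = n - p - k  # genome start of the reverse-complement k-mer
                if i < j:
                    by_anti.setdefault(i + j, []).append(i)
    for anti, starts in by_anti.items():
        starts = sorted(set(starts))
        for first, last in _chain(starts, k, max_gap):
            length = last + k - first
            if length < min_seg_len:
                continue
            a = (first, first + length)
            b = (anti - last, anti - first + k)
            if a[0] > b[0]:
                a, b = b, a
            seg_a = text[a[0] : a[1]]
            seg_b = revcomp(text[b[0] : b[1]])
            segments.append(
                MatchSegment(
                    span_a=a, span_b=b, orientation="inverted", length=length,
                    identity=_identity(seg_a, seg_b),
                )
            )

    uniq = sorted(set(segments), key=lambda s: (s.span_a, s.span_b, s.orientation))
    return uniq


def _merge_intervals(spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s in sorted(spans):
        if merged and s[0] <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], s[1]))
        else:
            merged.append(s)
    return merged


def detect_units(
    matches: list[MatchSegment],
    annotation: list[GeneFeature] | None = None,
) -> list[DuplicationUnit]:
    """Group intervals connected by match segments (single linkage, with
    overlapping intervals merged) into duplication units; each unit reports
    its member spans, orientation pattern and the genes each span contains."""
    spans: list[tuple[int, int]] = []
    edges: list[tuple[int, int]] = []
    for m in matches:
        spans.append(m.span_a)
        spans.append(m.span_b)
        edges.append((len(spans) - 2, len(spans) - 1))
    parent = list(range(len(spans)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    for a, b in edges:
        union(a, b)
    order = sorted(range(len(spans)), key=lambda i: spans[i])
    for prev, cur in zip(order, order[1:]):
        if spans[cur][0] < spans[prev][1]:  # overlapping intervals: same copy
            union(prev, cur)
    groups: dict[int, list[int]] = {}
    for i in range(len(spans)):
        groups.setdefault(find(i), []).append(i)

    units: list[DuplicationUnit] = []
    for members in groups.values():
        merged = _merge_intervals([spans[i] for i in members])
        if len(merged) < 2:
            continue
        orientations = {
            m.orientation
            for m in matches
            if any(m.span_a[0] >= s0 and m.span_a[1] <= s1 for s0, s1 in merged)
            and any(m.span_b[0] >= s0 and m.span_b[1] <= s1 for s0, s1 in merged)
        }
        pattern = orientations.pop() if len(orientations) == 1 else "mixed"
        genes: list[list[str]] = []
        if annotation is not None:
            for s0, s1 in merged:
                genes.append(
                    [
                        f.label
                        for f in annotation
                        if f.span[0] < s1 and s0 < f.span[1]
                    ]
                )
        units.append(
            DuplicationUnit(member_spans=merged, orientation_pattern=pattern, genes=genes)
        )
    units.sort(key=lambda u: u.member_spans[0])
    return units


def render_dotplot(
    matches: list[MatchSegment],
    path: str,
    seq_len: int | None = None,
) -> list[tuple[tuple[int, int], tuple[int, int], str]]:
    """Render matches as a dot-plot: direct segments parallel to the main
    diagonal (blue), inverted segments orthogonal (red).  Returns the plotted
    line coordinates ((x0, x1), (y0, y1), orientation) for testability."""
    if seq_len is None:
        seq_len = max((m.span_b[1] for m in matches), default=1)
    lines: list[tuple[tuple[int, int], tuple[int, int], str]] = []
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.plot([0, seq_len], [0, seq_len], color="0.7", lw=0.5)
    for m in matches:
        if m.orientation == "direct":
            xs = (m.span_a[0], m.span_a[1])
            ys = (m.span_b[0], m.span_b[1])
            color = "tab:blue"
        else:
            xs = (m.span_a[0], m.span_a[1])
            ys = (m.span_b[1], m.span_b[0])
            color = "tab:red"
        ax.plot(xs, ys, color=color, lw=1.0)
        ax.plot(ys, xs, color=color, lw=1.0)
        lines.append((xs, ys, m.orientation))
    ax.set_xlim(0, seq_len)
    ax.set_ylim(0, seq_len)
    ax.set_xlabel("position (nt)")
    ax.set_ylabel("position (nt)")
    ax.set_title("self-comparison dot plot")
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return lines
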