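"""Subgroup clustering (75% rule), same-gene matching (97% rule) and the
structure-based fallback for heavily defective pseudogenes.

The identity metric is a global, end-gap-free pairwise alignment; identity is
matches divided by alignment columns (columns gapped in exactly one sequence
count against identity, columns gapped in both cannot occur pairwise).  This
definition is deterministic and declared in all output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import PairwiseAligner

from .params import Params

__all__ = [
    "IdentityMatrix",
    "SubgroupAssignment",
    "pairwise_identity",
    "identity_matrix",
    "cluster_subgroups",
    "match_same_gene",
]


def _identity_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    # end-gap-free: overhangs are not penalised
    try:
        aligner.end_insertion_score = 0
        aligner.end_deletion_score = 0
    except AttributeError:  # older Biopython naming
        aligner.target_end_gap_score = 0
        aligner.query_end_gap_score = 0
    return aligner


_ALIGNER = _identity_aligner()


def pairwise_identity(a: str, b: str) -> float:
    """Percent nucleotide identity under end-gap-free global alignment.

    Symmetric; identical strings give 100.0; a single substitution among
    n aligned columns gives 100 * (n-1)/n.
    """
    if not a or not b:
        raise ValueError("both sequences must be non-empty")
    a, b = a.upper(), b.upper()
    if a == b:
        return 100.0
    aln = _ALIGNER.align(a, b)[0]
    ta, qa = aln.aligned
    matches = 0
    columns = 0
    prev_t, prev_q = None, None
    for (t0, t1), (q0, q1) in zip(ta, qa):
        if prev_t is not None:
            # interior gap columns: gapped in exactly one sequence
            columns += max(t0 - prev_t, q0 - prev_q)
        matches += sum(x == y for x, y in zip(a[t0:t1], b[q0:q1]))
        columns += t1 - t0
        prev_t, prev_q = t1, q1
    # end overhangs count as columns too (gapped in one sequence)
    if len(ta):
        columns += ta[0][0] + qa[0][0]
        columns += (len(a) - ta[-1][1]) + (len(b) - qa[-1][1])
    else:
        columns = max(len(a), len(b))
    return 100.0 * matches / columns if columns else 0.0


@dataclass
class IdentityMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("identity matrix must be symmetric")
        if not np.allclose(np.diag(v), 100.0):
            raise ValueError("identity matrix diagonal must be 100")
        if v.min() < 0 or v.max() > 100:
            raise ValueError("identities must lie in [0, 100]")
        self.values = v

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])


def identity_matrix(labels: list[str], seqs: list[str]) -> IdentityMatrix:
    n = len(labels)
    values = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            ident = pairwise_identity(seqs[i], seqs[j])
            values[i, j] = values[j, i] = ident
    return IdentityMatrix(labels=labels, values=values)


@dataclass
class SubgroupAssignment:
    subgroup_of: dict[str, str]
    method_of: dict[str, str] = field(default_factory=dict)  # identity | structural_fallback

    def members(self, subgroup: str) -> list[str]:
        return sorted(g for g, s in self.subgroup_of.items() if s == subgroup)

    @property
    def partition(self) -> set[frozenset[str]]:
        groups: dict[str, set[str]] = {}
        for g, s in self.subgroup_of.items():
            groups.setdefault(s, set()).add(g)
        return {frozenset(v) for v in groups.values()}


def _single_linkage(labels: list[str], values: np.ndarray, threshold: float) -> list[list[str]]:
    parent = list(range(len(labels)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            if values[i, j] > threshold:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    clusters: dict[int, list[str]] = {}
    for i, lab in enumerate(labels):
        clusters.setdefault(find(i), []).append(lab)
    # deterministic order: by smallest member label
    return sorted(clusters.values(), key=lambda c: min(c))


def cluster_subgroups(
    labels: list[str],
    vregion_seqs: dict[str, str],
    params: Params,
    full_length_seqs: dict[str, str] | None = None,
    fallback_labels: set[str] | None = None,
) -> SubgroupAssignment:
    """Single-linkage clustering at > subgroup_identity_threshold on V-REGION
    identity.

    Genes listed in ``fallback_labels`` (or lacking a usable V-REGION) are
    placed by the structural fallback: highest full-length
    (L-PART1 + intron + V-EXON) identity to an existing cluster, flagged with
    method ``structural_fallback``.  Order-invariant: internally sorted.
    """
    fallback_labels = set(fallback_labels or ())
    primary = sorted(l for l in labels if l not in fallback_labels and l in vregion_seqs)
    deferred = sorted(l for l in labels if l not in primary)
    mat = identity_matrix(primary, [vregion_seqs[l] for l in primary])
    clusters = _single_linkage(primary, mat.values, params.subgroup_identity_threshold)
    subgroup_of: dict[str, str] = {}
    method_of: dict[str, str] = {}
    for idx, members in enumerate(clusters, start=1):
        for m in members:
            subgroup_of[m] = f"SG{idx:02d}"
            method_of[m] = "identity"
    for lab in deferred:
        if full_length_seqs is None or lab not in full_length_seqs:
            raise ValueError(f"no full-length sequence for fallback gene {lab!r}")
        best_sub, best_ident = None, -1.0
        for other in primary:
            if other not in (full_length_seqs or {}):
                continue
            ident = pairwise_identity(full_length_seqs[lab], full_length_seqs[other])
            if ident > best_ident:
                best_sub, best_ident = subgroup_of[other], ident
        if best_sub is None:
            best_sub = f"SG{len(clusters) + 1 + deferred.index(lab):02d}"
        subgroup_of[lab] = best_sub
        method_of[lab] = "structural_fallback"
    return SubgroupAssignment(subgroup_of=subgroup_of, method_of=method_of)


def match_same_gene(
    set_a: dict[str, str], set_b: dict[str, str], params: Params
) -> tuple[list[tuple[str, str, float]], list[str], list[str]]:
    """Greedy best-first one-to-one matching of two gene sets at
    > same_gene_identity_threshold.

    Returns (matches, unmatched_a, unmatched_b); matches are
    (label_a, label_b, identity) in descending identity, ties broken by label
    order.  Unmatched genes on either side are the "distinct gene / assembly
    gap" situations.
    """
    if not set_a or not set_b:
        raise ValueError("both gene sets must be non-empty")
    pairs: list[tuple[float, str, str]] = []
    for la in sorted(set_a):
        for lb in sorted(set_b):
            ident = pairwise_identity(set_a[la], set_b[lb])
            if ident > params.same_gene_identity_threshold:
                pairs.append((ident, la, lb))
    pairs.sort(key=lambda p: (-p[0], p[1], p[2]))
    used_a: set[str] = set()
    used_b: set[str] = set()
    matches: list[tuple[str, str, float]] = []
    for ident, la, lb in pairs:
        if la in used_a or lb in used_b:
            continue
        used_a.add(la)
        used_b.add(lb)
        matches.append((la, lb, ident))
    unmatched_a = sorted(set(set_a) - used_a)
    unmatched_b = sorted(set(set_b) - used_b)
    return matches, unmatched_a, unmatched_b
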