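"""p-distance (pairwise deletion), neighbour-joining and bootstrap support.

Distances are proportions of differing sites per compared site; for each pair,
sites gapped or ambiguous in either sequence are removed (pairwise deletion).
Tree construction is the Saitou-Nei neighbour-joining algorithm with a
deterministic tie-break (lowest leaf-label pair); negative branch lengths are
clamped to zero and counted.  Bootstrap support resamples alignment columns
with replacement and reports, for every internal bipartition of the full-data
tree, the percentage of replicate trees containing it.

Multiple alignment construction is out of scope (input is pre-aligned FASTA);
:func:`trivial_alignment` covers the simulator's substitution-only fixtures,
which are already column-aligned by construction.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass

import numpy as np
from skbio import TreeNode

from .features import SeqRecord
from .params import Params

__all__ = [
    "Alignment",
    "trivial_alignment",
    "p_distance_matrix",
    "nj_tree",
    "bootstrap_support",
    "check_monophyly",
    "tree_to_newick",
    "tree_from_newick",
]

log = logging.getLogger(__name__)

_VALID_SITE = set("ACGT")


@dataclass
class Alignment:
    labels: list[str]
    seqs: list[str]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.seqs):
            raise ValueError("labels and sequences differ in number")
        if len({len(s) for s in self.seqs}) > 1:
            raise ValueError("alignment rows must have equal length")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate labels in alignment")

    @property
    def n_columns(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def resample_columns(self, rng: np.random.Generator) -> "Alignment":
        cols = rng.integers(0, self.n_columns, size=self.n_columns)
        seqs = ["".join(s[c] for c in cols) for s in self.seqs]
        return Alignment(labels=list(self.labels), seqs=seqs)


def trivial_alignment(records: list[SeqRecord]) -> Alignment:
    """Treat equal-length ungapped sequences as already aligned."""
    if len({len(r.seq) for r in records}) > 1:
        raise ValueError("sequences differ in length; supply a real alignment")
    return Alignment(labels=[r.id for r in records], seqs=[r.seq for r in records])


def p_distance_matrix(aln: Alignment) -> tuple[list[str], np.ndarray]:
    """d(i,j) = differing sites / compared sites under pairwise deletion."""
    n = len(aln.labels)
    if n < 2:
        raise ValueError("need at least two sequences")
    arrs = [np.frombuffer(s.upper().encode(), dtype=np.uint8) for s in aln.seqs]
    valid = [
        np.isin(a, np.frombuffer("ACGT".encode(), dtype=np.uint8)) for a in arrs
    ]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            compared = int(both.sum())
            if compared == 0:
                raise ValueError(
                    f"no comparable sites between {aln.labels[i]!r} and {aln.labels[j]!r}"
                )
            diff = int((arrs[i][both] != arrs[j][both]).sum())
            d[i, j] = d[j, i] = diff / compared
    return list(aln.labels), d


def _check_distance_matrix(d: np.ndarray) -> None:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0):
        raise ValueError("distance matrix diagonal must be zero")


def nj_tree(labels: list[str], dist: np.ndarray) -> TreeNode:
    """Saitou-Nei neighbour joining with deterministic tie-breaks.

    Returns an unrooted tree as a :class:`skbio.TreeNode` with a trifurcating
    root; ``tree.total_branch_length_`` carries the sum of branch lengths and
    ``tree.n_clamped_`` the number of negative lengths clamped to zero.
    """
    _check_distance_matrix(dist)
    n = len(labels)
    if n < 3:
        raise ValueError("need at least three taxa")
    d = np.asarray(dist, dtype=float).copy()
    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in labels]
    minleaf: list[str] = list(labels)
    total_length = 0.0
    clamped = 0

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += 1
            log.debug("negative branch length %.6g clamped to 0", x)
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                key = (q, *sorted((minleaf[i], minleaf[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = clamp(d[i, j] / 2 + (r[i] - r[j]) / (2 * (m - 2)))
        lj = clamp(d[i, j] - (d[i, j] / 2 + (r[i] - r[j]) / (2 * (m - 2))))
        total_length += li + lj
        parent = TreeNode()
        ni, nj_ = nodes[i], nodes[j]
        ni.length, nj_.length = li, lj
        parent.extend([ni, nj_])
        new_d = np.zeros((m - 1, m - 1))
        keep = [k for k in range(m) if k not in (i, j)]
        for a, ka in enumerate(keep):
            for b_, kb in enumerate(keep):
                new_d[a, b_] = d[ka, kb]
        for a, ka in enumerate(keep):
            du = (d[i, ka] + d[j, ka] - d[i, j]) / 2
            new_d[a, m - 2] = new_d[m - 2, a] = du
        d = new_d
        new_minleaf = [minleaf[k] for k in keep] + [min(minleaf[i], minleaf[j])]
        nodes = [nodes[k] for k in keep] + [parent]
        minleaf = new_minleaf

    # final three-way join (unrooted): l_i = (d_ij + d_ik - d_jk) / 2
    l0 = clamp((d[0, 1] + d[0, 2] - d[1, 2]) / 2)
    l1 = clamp((d[0, 1] + d[1, 2] - d[0, 2]) / 2)
    l2 = clamp((d[0, 2] + d[1, 2] - d[0, 1]) / 2)
    total_length += l0 + l1 + l2
    root = TreeNode()
    for node, ln in zip(nodes, (l0, l1, l2)):
        node.length = ln
        root.append(node)
    root.total_branch_length_ = total_length
    root.n_clamped_ = clamped
    return root


def _bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Internal-edge bipartitions, each canonicalised as the smaller side
    (ties broken lexicographically)."""
    leaves = frozenset(t.name for t in tree.tips())
    splits: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = leaves - side
        if not side or not other:
            continue
        canon = min((side, other), key=lambda s: (len(s), sorted(s)))
        splits.add(canon)
    return splits


def bootstrap_support(
    aln: Alignment, n_reps: int, seed: int, params: Params | None = None
) -> TreeNode:
    """NJ tree of the full alignment with bootstrap percentages on internal
    nodes (column resampling with replacement, seeded and reproducible).

    If all pairwise distances are zero the supports are undefined; the tree is
    returned with ``degenerate_`` set instead of supports.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    labels, d = p_distance_matrix(aln)
    tree = nj_tree(labels, d)
    if np.allclose(d, 0):
        tree.degenerate_ = True
        return tree
    tree.degenerate_ = False
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {s: 0 for s in _bipartitions(tree)}
    for _ in range(n_reps):
        rep = aln.resample_columns(rng)
        try:
            rep_labels, rep_d = p_distance_matrix(rep)
        except ValueError:
            continue  # a replicate with an incomparable pair is skipped
        rep_tree = nj_tree(rep_labels, rep_d)
        rep_splits = _bipartitions(rep_tree)
        for s in counts:
            if s in rep_splits:
                counts[s] += 1
    leaves = frozenset(t.name for t in tree.tips())
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        canon = min((side, leaves - side), key=lambda s: (len(s), sorted(s)))
        if canon in counts:
            node.name = str(int(round(100 * counts[canon] / n_reps)))
    return tree


def check_monophyly(tree: TreeNode, label_groups: dict[str, set[str]]) -> dict[str, bool]:
    """A group is monophyletic iff some edge bipartition isolates exactly it."""
    leaves = {t.name for t in tree.tips()}
    for name, group in label_groups.items():
        unknown = set(group) - leaves
        if unknown:
            raise ValueError(f"group {name!r} has unknown labels {sorted(unknown)}")
    sides: set[frozenset[str]] = set()
    for node in tree.traverse(include_self=False):
        side = frozenset(t.name for t in node.tips()) if not node.is_tip() else frozenset({node.name})
        sides.add(side)
        sides.add(frozenset(leaves) - side)
    out = {}
    for name, group in label_groups.items():
        fg = frozenset(group)
        out[name] = len(fg) in (1, len(leaves)) or fg in sides
    return out


def tree_to_newick(tree: TreeNode) -> str:
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def tree_from_newick(text: str) -> TreeNode:
    return TreeNode.read(io.StringIO(text), format="newick")
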