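"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation paths they check: the D-segment
oracle enumerates every valid assignment recursively; the RS oracle is a
naive sliding-window scan; the p-distance oracle is a per-site loop; additive
distance matrices are built directly from randomly generated trees.
"""

from __future__ import annotations

import numpy as np

NT = list("ACGT")


# ---------------------------------------------------------------------------
# exhaustive D-assignment search


def enumerate_d_candidates(junction: str, d_refs, min_len: int):
    junction = junction.upper()
    cands = []
    for di, (_lab, d) in enumerate(d_refs):
        d = d.upper()
        for i in range(len(junction)):
            for j in range(len(d)):
                L = 0
                while i + L < len(junction) and j + L < len(d) and junction[i + L] == d[j + L]:
                    L += 1
                for ln in range(min_len, L + 1):
                    cands.append((i, i + ln, di, j))
    return sorted(cands)


def oracle_d_assignment(junction: str, d_refs, min_len: int):
    """Exhaustively enumerate all non-overlapping, order-respecting
    assignments; return the best under (max total nt, fewest segments,
    leftmost placement, earliest labels, earliest d offsets)."""
    cands = enumerate_d_candidates(junction, d_refs, min_len)
    best = None

    def consider(prefix):
        nonlocal best
        key = (
            -sum(c[1] - c[0] for c in prefix),
            len(prefix),
            tuple(c[0] for c in prefix),
            tuple(c[2] for c in prefix),
            tuple(c[3] for c in prefix),
        )
        if best is None or key < best[0]:
            best = (key, list(prefix))

    def rec(prefix, min_start, min_d):
        consider(prefix)
        for c in cands:
            if c[0] >= min_start and c[2] >= min_d:
                rec(prefix + [c], c[1], c[2] + 1)

    rec([], 0, 0)
    return best[1]


def random_d_refs(rng: np.random.Generator, lengths=(13, 11, 9, 13, 13, 11)):
    return [(f"D{i + 1}", "".join(rng.choice(NT, L))) for i, L in enumerate(lengths)]


def random_junction(rng: np.random.Generator, d_refs, max_len: int = 40) -> str:
    """Half purely random, half containing planted D fragments."""
    if rng.random() < 0.5:
        n = int(rng.integers(5, max_len + 1))
        return "".join(rng.choice(NT, n))
    parts = []
    for _ in range(int(rng.integers(1, 4))):
        _, d = d_refs[int(rng.integers(len(d_refs)))]
        a = int(rng.integers(0, len(d) - 4))
        b = int(rng.integers(a + 5, len(d) + 1))
        parts.append(d[a:b])
        parts.append("".join(rng.choice(NT, int(rng.integers(0, 4)))))
    out = "".join(parts)[:max_len]
    if len(out) < 5:
        out += "".join(rng.choice(NT, 5 - len(out)))
    return out


# ---------------------------------------------------------------------------
# naive RS sliding-window scan


def oracle_rs_hits(text: str, heptamer: str, nonamer: str, spacer: int,
                   max_h: int, max_n: int, slacks=(0, -1, 1)):
    """Set of (heptamer_start, strand) with mismatch counts within budget."""

    def mism(a, b):
        return sum(x != y for x, y in zip(a, b))

    def revcomp(s):
        comp = str.maketrans("ACGT", "TGCA")
        return s.translate(comp)[::-1]

    text = text.upper()
    hits = set()
    for slack in slacks:
        gap = spacer + slack
        # forward: heptamer + gap + nonamer
        for i in range(len(text) - len(heptamer) - gap - len(nonamer) + 1):
            h = text[i : i + len(heptamer)]
            n = text[i + len(heptamer) + gap : i + len(heptamer) + gap + len(nonamer)]
            if mism(h, heptamer) <= max_h and mism(n, nonamer) <= max_n:
                hits.add((i, "+"))
        # reverse: nonamer_rc + gap + heptamer_rc
        nrc, hrc = revcomp(nonamer), revcomp(heptamer)
        for i in range(len(text) - len(nrc) - gap - len(hrc) + 1):
            n = text[i : i + len(nrc)]
            h = text[i + len(nrc) + gap : i + len(nrc) + gap + len(hrc)]
            if mism(n, nrc) <= max_n and mism(h, hrc) <= max_h:
                hits.add((i + len(nrc) + gap, "-"))
    return hits


# ---------------------------------------------------------------------------
# random trees with additive distances


def random_additive_matrix(n: int, rng: np.random.Generator):
    """Random binary tree over n leaves; returns (distance matrix, splits)."""
    children: dict[int, tuple[int, int]] = {}
    lengths: dict[int, float] = {i: float(rng.uniform(0.05, 1.0)) for i in range(n)}
    active = list(range(n))
    nxt = n
    while len(active) > 1:
        i, j = sorted(rng.choice(len(active), 2, replace=False))
        a, b = active[i], active[j]
        children[nxt] = (a, b)
        lengths[nxt] = float(rng.uniform(0.05, 1.0))
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    root = active[0]
    D = np.zeros((n, n))

    def walk(x):
        """Return {leaf: distance to x}; fill D for leaf pairs split at x."""
        if x < n:
            return {x: 0.0}
        a, b = children[x]
        da = {k: v + lengths[a] for k, v in walk(a).items()}
        db = {k: v + lengths[b] for k, v in walk(b).items()}
        for ka, va in da.items():
            for kb, vb in db.items():
                D[ka, kb] = D[kb, ka] = va + vb
        return {**da, **db}

    walk(root)

    leaves_all = frozenset(f"t{i}" for i in range(n))

    def leafset(x):
        if x < n:
            return frozenset({f"t{x}"})
        a, b = children[x]
        return leafset(a) | leafset(b)

    splits = set()
    for x in children:
        for side in children[x]:
            s = leafset(side)
            o = leaves_all - s
            if len(s) >= 2 and len(o) >= 2:
                splits.add(min((s, o), key=lambda q: (len(q), sorted(q))))
    return D, splits
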