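"""Brute-force oracles and random generators shared across tests.

Everything here is deliberately naive — position-by-position scans,
exhaustive enumerations, literal formula transcriptions — so it stays
independent of the library code it checks.
"""

from __future__ import annotations

import collections

import numpy as np

from mcptyper.seqcore import base_set, revcomp

IUPAC = "ACGTRYSWKMBDHVN"


def random_degenerate(rng, length, alphabet=IUPAC):
    return "".join(alphabet[rng.integers(0, len(alphabet))] for _ in range(length))


def random_dna(rng, length):
    return "".join("ACGT"[rng.integers(0, 4)] for _ in range(length))


def brute_force_expand(pattern):
    """Expansion by explicit per-position recursion."""
    if not pattern:
        return {""}
    rest = brute_force_expand(pattern[1:])
    return {b + tail for b in sorted(base_set(pattern[0])) for tail in rest}


def brute_force_sites(pattern, template, max_mismatch, clamp_len, clamp_max):
    """All sites on both strands via a per-offset, per-position scan.

    Returns tuples (strand, start, end, mismatches, clamp_mismatches) in
    plus-strand coordinates.  Template N matches nothing.
    """
    out = []
    L = len(pattern)
    for strand in "+-":
        probe = pattern if strand == "+" else revcomp(pattern)
        clamp_positions = (
            set(range(L - clamp_len, L)) if strand == "+" else set(range(clamp_len))
        )
        for start in range(len(template) - L + 1):
            mm = 0
            cmm = 0
            for k in range(L):
                base = template[start + k]
                hit = base != "N" and base in base_set(probe[k])
                if not hit:
                    mm += 1
                    if k in clamp_positions:
                        cmm += 1
            if mm <= max_mismatch and cmm <= clamp_max:
                out.append((strand, start, start + L, mm, cmm))
    return sorted(out, key=lambda s: (s[1], s[0]))


def brute_force_amplicons(fw_sites, rev_sites, min_len, max_len):
    """Convergent combinations as (start, end) intervals, both orientations."""
    out = []
    for f in fw_sites:
        for r in rev_sites:
            if f[0] == "+" and r[0] == "-" and f[1] < r[1]:
                length = r[2] - f[1]
                if min_len <= length <= max_len:
                    out.append((f[1], r[2]))
            if r[0] == "+" and f[0] == "-" and r[1] < f[1]:
                length = f[2] - r[1]
                if min_len <= length <= max_len:
                    out.append((r[1], f[2]))
    return sorted(out)


def brute_force_dotplot(a, b, word_len, min_identity):
    hits = []
    for i in range(len(a) - word_len + 1):
        for j in range(len(b) - word_len + 1):
            same = sum(a[i + k] == b[j + k] for k in range(word_len))
            if same / word_len >= min_identity:
                hits.append((i, j))
    return hits


def random_additive_tree(rng, n):
    """A random unrooted binary tree with positive edge lengths.

    Returns (labels, distance matrix, bipartition set).  Built by
    attaching each new leaf to a uniformly random existing edge.
    """
    labels = [f"t{i}" for i in range(n)]
    adj = collections.defaultdict(dict)

    def connect(u, v, w):
        adj[u][v] = w
        adj[v][u] = w

    def disconnect(u, v):
        del adj[u][v]
        del adj[v][u]

    connect("i0", labels[0], rng.uniform(0.1, 1.0))
    connect("i0", labels[1], rng.uniform(0.1, 1.0))
    connect("i0", labels[2], rng.uniform(0.1, 1.0))
    next_internal = 1
    for k in range(3, n):
        edges = sorted(
            (u, v) for u in adj for v in adj[u] if u < v
        )
        u, v = edges[rng.integers(0, len(edges))]
        w = adj[u][v]
        disconnect(u, v)
        mid = f"i{next_internal}"
        next_internal += 1
        split = w * rng.uniform(0.2, 0.8)
        connect(u, mid, split)
        connect(v, mid, w - split)
        connect(mid, labels[k], rng.uniform(0.1, 1.0))

    def distances_from(source):
        seen = {source: 0.0}
        stack = [source]
        while stack:
            x = stack.pop()
            for y, w in adj[x].items():
                if y not in seen:
                    seen[y] = seen[x] + w
                    stack.append(y)
        return seen

    D = np.zeros((n, n))
    for i, a in enumerate(labels):
        d = distances_from(a)
        for j, b in enumerate(labels):
            D[i, j] = d[b]
    D = (D + D.T) / 2.0  # remove float asymmetry from per-source traversal

    # bipartitions: removing each internal-internal edge splits the leaves
    ref = sorted(labels)[0]
    total = set(labels)
    bps = set()
    for u in list(adj):
        for v in list(adj[u]):
            if u >= v:
                continue
            # leaves on v's side when edge (u, v) is removed; a tree has
            # no other path between the sides, so skipping that one edge
            # during traversal isolates the side.
            seen = {v}
            stack = [v]
            while stack:
                x = stack.pop()
                for y in adj[x]:
                    if (x, y) == (v, u):
                        continue
                    if y not in seen:
                        seen.add(y)
                        stack.append(y)
            side = frozenset(s for s in seen if s in total)
            if ref in side:
                side = frozenset(total - side)
            if 2 <= len(side) <= n - 2:
                bps.add(side)
    return labels, D, bps
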