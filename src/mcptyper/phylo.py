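"""MCP-sequence comparison: distances, neighbor joining, dotplots, typing.

Confirms group assignments from the sequence side: a word dotplot shows
the block structure of the reference capsid proteins, a neighbor-joining
(NJ) tree with bootstrap support shows that groups form distinct clusters,
and nearest-reference assignment classifies a new sequence by its closest
labelled reference.

Numerical conventions:

* distances default to the p-distance (fraction of differing aligned
  positions) with pairwise deletion of gap columns; a Poisson-corrected
  distance is available behind ``model="poisson"``;
* NJ follows the standard Q-criterion agglomeration with deterministic
  tie-breaking (first minimal pair in current row/column order); negative
  branch lengths are clamped to zero and the clamped deficit is logged;
* bootstrap replicate ``r`` draws its columns from a fresh RNG seeded
  ``seed + r``, which makes runs reproducible and parallelisable;
* supports are percentages in [0, 100]; collapsing below a threshold
  contracts the edge and adds its length onto the promoted children so
  leaf-to-leaf path lengths are preserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd
from Bio import Align

from .codehop import ProteinAlignment

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "TreeNode",
    "PhyloTree",
    "DotplotHits",
    "Assignment",
    "p_distance_matrix",
    "neighbor_joining",
    "bootstrap_support",
    "collapse_low_support",
    "dotplot",
    "assign_group",
]

_GAP = "-"


@dataclass
class DistanceMatrix:
    """A labelled symmetric distance matrix with zero diagonal."""

    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if m.shape != (n, n):
            raise ValueError(f"matrix shape {m.shape} does not fit {n} labels")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have a zero diagonal")
        if (m < -1e-12).any():
            raise ValueError("distance matrix must be non-negative")
        self.matrix = m

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)


@dataclass
class TreeNode:
    name: str = ""
    length: float = 0.0
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for child in self.children:
            out.extend(child.leaves())
        return out

    def copy(self) -> "TreeNode":
        return TreeNode(
            self.name,
            self.length,
            self.support,
            [c.copy() for c in self.children],
        )


@dataclass
class PhyloTree:
    """An (unrooted) phylogeny, stored with an arbitrary trifurcating root.

    Internal-edge bootstrap supports live on the internal nodes, as
    percentages in [0, 100].
    """

    root: TreeNode

    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.root.leaves()]

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.root.copy())

    def _internal_nodes(self) -> list[TreeNode]:
        out: list[TreeNode] = []

        def walk(node: TreeNode):
            for child in node.children:
                if not child.is_leaf:
                    out.append(child)
                    walk(child)

        walk(self.root)
        return out

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial bipartitions, canonicalised as the side that does
        not contain the alphabetically first leaf."""
        all_leaves = sorted(self.leaf_names())
        ref = all_leaves[0]
        total = set(all_leaves)
        out: set[frozenset] = set()
        for node in self._internal_nodes():
            side = frozenset(leaf.name for leaf in node.leaves())
            if ref in side:
                side = frozenset(total - side)
            if 2 <= len(side) <= len(total) - 2:
                out.add(side)
        return out

    def bipartition_nodes(self) -> dict[frozenset, TreeNode]:
        all_leaves = sorted(self.leaf_names())
        ref = all_leaves[0]
        total = set(all_leaves)
        out: dict[frozenset, TreeNode] = {}
        for node in self._internal_nodes():
            side = frozenset(leaf.name for leaf in node.leaves())
            if ref in side:
                side = frozenset(total - side)
            if 2 <= len(side) <= len(total) - 2:
                out[side] = node
        return out

    def pairwise_distances(self) -> dict[tuple[str, str], float]:
        """Leaf-to-leaf path lengths, keyed by sorted name pairs."""
        dists: dict[tuple[str, str], float] = {}

        def walk(node: TreeNode) -> dict[str, float]:
            if node.is_leaf:
                return {node.name: 0.0}
            below: dict[str, float] = {}
            child_maps = []
            for child in node.children:
                cmap = {k: v + child.length for k, v in walk(child).items()}
                child_maps.append(cmap)
            for i, m1 in enumerate(child_maps):
                for m2 in child_maps[i + 1 :]:
                    for a, da in m1.items():
                        for b, db in m2.items():
                            key = (a, b) if a < b else (b, a)
                            dists[key] = da + db
                below = {k: v for cmap in child_maps for k, v in cmap.items()}
            return below

        walk(self.root)
        return dists

    def to_newick(self, include_support: bool = True) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.10g}"
            inner = ",".join(fmt(c) for c in node.children)
            label = ""
            if include_support and node.support is not None:
                label = f"{node.support:g}"
            elif node.name:
                label = node.name
            return f"({inner}){label}:{node.length:.10g}"

        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"


def _encode_rows(msa: ProteinAlignment) -> np.ndarray:
    return np.array([np.frombuffer(r.encode(), dtype=np.uint8) for r in msa.rows])


def p_distance_matrix(
    msa: ProteinAlignment, model: str = "p"
) -> DistanceMatrix:
    """Pairwise distances with pairwise deletion of gap columns.

    ``model="p"`` gives the plain p-distance (mismatches / compared
    columns); ``model="poisson"`` applies -ln(1 - p).  Raises when a pair
    shares no gap-free columns, or (poisson) when p = 1.
    """
    if msa.n < 3:
        raise ValueError("need at least 3 sequences for a distance matrix")
    enc = _encode_rows(msa)
    gap = ord(_GAP)
    n = msa.n
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            usable = (enc[i] != gap) & (enc[j] != gap)
            total = int(usable.sum())
            if total == 0:
                raise ValueError(
                    f"sequences {msa.ids[i]!r} and {msa.ids[j]!r} share no "
                    "comparable columns"
                )
            p = float((enc[i][usable] != enc[j][usable]).sum()) / total
            if model == "p":
                d[i, j] = d[j, i] = p
            elif model == "poisson":
                if p >= 1.0:
                    raise ValueError(
                        f"p-distance 1.0 between {msa.ids[i]!r} and "
                        f"{msa.ids[j]!r}: Poisson correction undefined"
                    )
                d[i, j] = d[j, i] = -np.log(1.0 - p)
            else:
                raise ValueError(f"unknown distance model {model!r}")
    return DistanceMatrix(list(msa.ids), d)


def _clamp_length(length: float, context: str) -> float:
    if length < 0:
        logger.debug("clamping negative branch length %.6g (%s)", length, context)
        return 0.0
    return length


def neighbor_joining(
    D: DistanceMatrix, trace: list | None = None
) -> PhyloTree:
    """Standard neighbor joining with deterministic tie-breaking.

    At each step the Q-criterion ``Q_ij = (m-2) d_ij - r_i - r_j`` is
    minimised over all active pairs; ties resolve to the first (row, col)
    pair in current order.  Branch lengths follow the standard formulas;
    negatives are clamped to zero.  If ``trace`` is a list, each step
    appends ``(active distance submatrix, chosen local (i, j))`` for
    oracle checking.
    """
    n = D.n
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    size = 2 * n
    M = np.zeros((size, size))
    M[:n, :n] = D.matrix
    nodes: list[TreeNode] = [TreeNode(name=l) for l in D.labels]
    active: list[int] = list(range(n))
    next_id = n
    while len(active) > 3:
        m = len(active)
        idx = np.array(active)
        sub = M[np.ix_(idx, idx)]
        r = sub.sum(axis=1)
        best: tuple[float, int, int] | None = None
        for a in range(m):
            for b in range(a + 1, m):
                q = (m - 2) * sub[a, b] - r[a] - r[b]
                if best is None or q < best[0]:
                    best = (q, a, b)
        assert best is not None
        _, a, b = best
        if trace is not None:
            trace.append((sub.copy(), (a, b)))
        i, j = active[a], active[b]
        dij = M[i, j]
        li = dij / 2.0 + (r[a] - r[b]) / (2.0 * (m - 2))
        lj = dij - li
        nodes[i].length = _clamp_length(li, f"join of {i} and {j}")
        nodes[j].length = _clamp_length(lj, f"join of {i} and {j}")
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes.append(parent)
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (M[i, k] + M[j, k] - dij)
            M[next_id, k] = M[k, next_id] = duk
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1
        if next_id >= size:  # pragma: no cover - capacity guard
            M = np.pad(M, ((0, size), (0, size)))
            size *= 2
    x, y, z = active
    dxy, dxz, dyz = M[x, y], M[x, z], M[y, z]
    nodes[x].length = _clamp_length((dxy + dxz - dyz) / 2.0, "final join")
    nodes[y].length = _clamp_length((dxy + dyz - dxz) / 2.0, "final join")
    nodes[z].length = _clamp_length((dxz + dyz - dxy) / 2.0, "final join")
    root = TreeNode(children=[nodes[x], nodes[y], nodes[z]])
    return PhyloTree(root)


def bootstrap_support(
    msa: ProteinAlignment,
    n_replicates: int = 100,
    seed: int = 0,
    model: str = "p",
) -> PhyloTree:
    """NJ tree on the full alignment, with bootstrap supports.

    Columns are resampled with replacement per replicate; replicate ``r``
    uses seed ``seed + r``.  Support of an internal edge is the percentage
    of usable replicates whose NJ tree contains the same bipartition.
    Replicates whose resampled alignment leaves some pair without
    comparable columns are skipped.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    full = neighbor_joining(p_distance_matrix(msa, model=model))
    nodes = full.bipartition_nodes()
    counts = {bp: 0 for bp in nodes}
    used = 0
    for r in range(n_replicates):
        rng = np.random.default_rng(seed + r)
        cols = rng.integers(0, msa.ncol, size=msa.ncol)
        rows = ["".join(row[c] for c in cols) for row in msa.rows]
        replicate = ProteinAlignment(list(msa.ids), rows)
        try:
            rep_tree = neighbor_joining(p_distance_matrix(replicate, model=model))
        except ValueError:
            continue
        used += 1
        rep_bps = rep_tree.bipartitions()
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    for bp, node in nodes.items():
        node.support = 100.0 * counts[bp] / used if used else 0.0
    return full


def collapse_low_support(
    tree: PhyloTree, threshold_percent: float = 50.0
) -> PhyloTree:
    """Contract internal edges whose support is below the threshold.

    Contraction discards the collapsed edge's length — the usual
    convention when creating polytomies — so leaf-to-leaf paths that
    crossed the edge shorten by that amount.  Leaves are never removed;
    the operation only merges nodes and is idempotent.
    """
    out = tree.copy()

    def walk(node: TreeNode):
        for child in node.children:
            walk(child)
        new_children: list[TreeNode] = []
        for child in node.children:
            if (
                not child.is_leaf
                and child.support is not None
                and child.support < threshold_percent
            ):
                new_children.extend(child.children)
            else:
                new_children.append(child)
        node.children = new_children

    walk(out.root)
    return out


@dataclass
class DotplotHits:
    """Word-match coordinates between two sequences."""

    id_a: str
    id_b: str
    word_len: int
    hits: list[tuple[int, int]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.hits, columns=["i", "j"])

    def transpose(self) -> "DotplotHits":
        return DotplotHits(
            self.id_b, self.id_a, self.word_len, [(j, i) for i, j in self.hits]
        )

    def render(self, ax=None):
        """Scatter the hits (matplotlib); returns the axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        if self.hits:
            xs, ys = zip(*self.hits)
            ax.plot(xs, ys, ".", markersize=1, color="black")
        ax.set_xlabel(self.id_a)
        ax.set_ylabel(self.id_b)
        ax.invert_yaxis()
        return ax


def dotplot(
    seq_a: str,
    seq_b: str,
    word_len: int = 10,
    min_identity: float = 1.0,
    id_a: str = "A",
    id_b: str = "B",
) -> DotplotHits:
    """All (i, j) where windows of ``word_len`` match at ``min_identity``.

    Window identity is position-by-position over the two words.  Defaults
    (word length 10, exact identity) suit protein comparisons where only
    within-group similarity should light up.
    """
    if word_len < 1:
        raise ValueError("word_len must be >= 1")
    a = np.frombuffer(seq_a.upper().encode(), dtype=np.uint8)
    b = np.frombuffer(seq_b.upper().encode(), dtype=np.uint8)
    na, nb = len(a) - word_len + 1, len(b) - word_len + 1
    if na <= 0 or nb <= 0:
        return DotplotHits(id_a, id_b, word_len, [])
    counts = np.zeros((na, nb), dtype=np.int32)
    for k in range(word_len):
        counts += a[k : k + na, None] == b[None, k : k + nb]
    ii, jj = np.nonzero(counts / word_len >= min_identity)
    return DotplotHits(id_a, id_b, word_len, list(zip(ii.tolist(), jj.tolist())))


@dataclass
class Assignment:
    """Nearest-reference classification of a query sequence."""

    group: str
    identity: float
    tie: bool
    scores: dict[str, float]  # best identity per group


_aligner_cache: dict[str, Align.PairwiseAligner] = {}


def _protein_aligner() -> Align.PairwiseAligner:
    if "protein" not in _aligner_cache:
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1.0
        aligner.mismatch_score = 0.0
        aligner.open_gap_score = -1.0
        aligner.extend_gap_score = -0.5
        _aligner_cache["protein"] = aligner
    return _aligner_cache["protein"]


def _alignment_identity(query: str, ref: str) -> float:
    aligner = _protein_aligner()
    alignment = aligner.align(query, ref)[0]
    identities = alignment.counts().identities
    return identities / max(len(query), len(ref))


def _word_identity(query: str, ref: str, word_len: int = 4) -> float:
    words_q = {query[i : i + word_len] for i in range(len(query) - word_len + 1)}
    words_r = {ref[i : i + word_len] for i in range(len(ref) - word_len + 1)}
    if not words_q or not words_r:
        return 0.0
    return len(words_q & words_r) / len(words_q | words_r)


def assign_group(
    query: str,
    references: Sequence[tuple[str, str]],
    method: str = "alignment",
    word_len: int = 4,
) -> Assignment:
    """Label a query with the group of its most similar reference.

    ``references`` is a sequence of (group label, sequence).  Identity is
    either global-alignment identity (identical aligned residues over the
    longer sequence length) or, with ``method="word"``, the Jaccard index
    of the two k-mer sets.  Ties go to the alphabetically first group and
    set the ``tie`` flag.
    """
    if not references:
        raise ValueError("reference set must be non-empty")
    if method == "alignment":
        score = _alignment_identity
    elif method == "word":
        def score(q, r):
            return _word_identity(q, r, word_len=word_len)
    else:
        raise ValueError(f"unknown assignment method {method!r}")
    best_per_group: dict[str, float] = {}
    for label, ref in references:
        s = score(query, ref)
        if s > best_per_group.get(label, -1.0):
            best_per_group[label] = s
    best = max(best_per_group.values())
    winners = sorted(g for g, s in best_per_group.items() if s >= best - 1e-12)
    return Assignment(
        group=winners[0],
        identity=best,
        tie=len(winners) > 1,
        scores=best_per_group,
    )
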