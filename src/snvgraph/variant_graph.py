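"""Single-nucleotide-variant graphs over unique-sequence tables.

For each read length, unique sequences become nodes and an edge joins every
pair at Hamming distance exactly one (a single substitution; no indels, no
cross-length edges).  The graph decomposes into connected subgraphs, each
with a designated *parent* — its most abundant member, assumed to be the
error-free source of its lower-abundance variant children.

Edge construction uses masked-key hashing: each length-L sequence emits L
keys, one per position with that position wildcarded.  Two sequences share a
key if and only if they are identical away from the masked position, so every
within-bucket pair is at Hamming distance exactly 1 (sequences are unique,
ruling out distance 0), and a distance-1 pair shares exactly one key.  This
is O(N·L) in the number of sequences rather than the O(N²·L) of all-pairs
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

from .preprocess import UniqueSequence

__all__ = [
    "VariantGraph",
    "Subgraph",
    "build_graph",
    "connected_subgraphs",
    "subgraph_size_summary",
    "hamming",
]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    return sum(x != y for x, y in zip(a, b))


@dataclass
class VariantGraph:
    """Nodes (unique sequences of one length) plus distance-1 edges."""

    nodes: list[UniqueSequence]
    edges: list[tuple[int, int]]
    length: int
    adjacency: list[list[int]] = field(repr=False, default_factory=list)

    def __post_init__(self) -> None:
        if not self.adjacency:
            adj: list[list[int]] = [[] for _ in self.nodes]
            for u, v in self.edges:
                adj[u].append(v)
                adj[v].append(u)
            self.adjacency = adj

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def neighbors(self, i: int) -> list[int]:
        return self.adjacency[i]


@dataclass
class Subgraph:
    """One connected component, with its parent (most abundant node).

    ``a_parent`` is the parent's abundance and ``a_total`` the component's
    total abundance; the parental abundance ratio ``a_parent / a_total`` is
    the selection statistic used when building the error model.
    """

    members: list[int]
    parent_index: int
    a_parent: int
    a_total: int

    @property
    def n_nodes(self) -> int:
        return len(self.members)

    @property
    def parent_ratio(self) -> float:
        return self.a_parent / self.a_total


def build_graph(table: Sequence[UniqueSequence]) -> VariantGraph:
    """Build the distance-1 graph for one length via masked-key hashing."""
    if not table:
        return VariantGraph([], [], 0)
    length = len(table[0].seq)
    seen: set[str] = set()
    for rec in table:
        if len(rec.seq) != length:
            raise ValueError("all sequences must share one length")
        if rec.seq in seen:
            raise ValueError(f"duplicate sequence {rec.seq!r}")
        seen.add(rec.seq)

    buckets: dict[str, list[int]] = {}
    for idx, rec in enumerate(table):
        s = rec.seq
        for pos in range(length):
            key = f"{pos}:{s[:pos]}*{s[pos + 1:]}"
            buckets.setdefault(key, []).append(idx)
    edges: list[tuple[int, int]] = []
    for bucket in buckets.values():
        if len(bucket) > 1:
            # all pairs in a bucket differ only at the masked position
            edges.extend(combinations(bucket, 2))
    edges = sorted({(min(u, v), max(u, v)) for u, v in edges})
    return VariantGraph(list(table), edges, length)


def connected_subgraphs(g: VariantGraph) -> list[Subgraph]:
    """Decompose the graph into connected components with designated parents.

    The parent is the most abundant member; ties break to the
    lexicographically smallest sequence so decomposition is deterministic.
    Singleton components are included.
    """
    seen = [False] * g.n_nodes
    out: list[Subgraph] = []
    for start in range(g.n_nodes):
        if seen[start]:
            continue
        stack = [start]
        seen[start] = True
        members = []
        while stack:
            u = stack.pop()
            members.append(u)
            for v in g.adjacency[u]:
                if not seen[v]:
                    seen[v] = True
                    stack.append(v)
        members.sort()
        parent = min(members, key=lambda i: (-g.nodes[i].abundance, g.nodes[i].seq))
        a_total = sum(g.nodes[i].abundance for i in members)
        out.append(Subgraph(members, parent, g.nodes[parent].abundance, a_total))
    return out


#: size-bin edges: singletons, 2-19, 20-39, 40 and above
SIZE_BINS = ((1, 1), (2, 19), (20, 39), (40, None))


def subgraph_size_summary(subgraphs: Iterable[Subgraph]) -> dict[str, int]:
    """Count components per size bin; returns bin counts plus the largest size."""
    counts = {"1": 0, "2-19": 0, "20-39": 0, "40+": 0}
    largest = 0
    for sg in subgraphs:
        n = sg.n_nodes
        largest = max(largest, n)
        if n == 1:
            counts["1"] += 1
        elif n <= 19:
            counts["2-19"] += 1
        elif n <= 39:
            counts["20-39"] += 1
        else:
            counts["40+"] += 1
    counts["largest"] = largest
    return counts


def write_edges(g: VariantGraph, path: str | Path) -> None:
    with open(path, "w") as fh:
        for u, v in g.edges:
            fh.write(f"{g.nodes[u].seq}\t{g.nodes[v].seq}\n")


def write_components(
    g: VariantGraph, subgraphs: Sequence[Subgraph], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("seq\tabundance\tcomponent_id\tis_parent\n")
        for cid, sg in enumerate(subgraphs):
            for i in sg.members:
                rec = g.nodes[i]
                fh.write(
                    f"{rec.seq}\t{rec.abundance}\t{cid}\t{int(i == sg.parent_index)}\n"
                )
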