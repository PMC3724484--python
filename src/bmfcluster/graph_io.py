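"""Flat-file I/O for protein-protein interaction networks and complex sets.

The formats are the plain tab-delimited conventions of the MIPS/DIP database
exports: an edge list with one interacting protein pair per line (extra
columns such as confidence scores are ignored), and a complex file with one
complex per line, ``name TAB member TAB member ...``.  Identifiers are
treated as opaque strings; no cross-database mapping is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "PPIGraph",
    "ComplexSet",
    "read_edge_list",
    "write_edge_list",
    "read_complexes",
    "write_clusters",
    "write_adjacency_mtx",
]


@dataclass(frozen=True)
class PPIGraph:
    """An undirected PPI network: named nodes plus a binary adjacency matrix.

    Nodes are ordered by first appearance in the input stream so that seeded
    downstream runs are reproducible across platforms.  The adjacency matrix
    is symmetric with a zero diagonal: self-interactions are dropped on load
    because a complex is defined by interactions between its members.
    """

    nodes: tuple[str, ...]
    adjacency: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if a.shape[0] != len(self.nodes):
            raise ValueError("adjacency size does not match node count")
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node identifiers")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        if (a != a.T).any():
            raise ValueError("adjacency must be symmetric")
        if np.diagonal(a).any():
            raise ValueError("adjacency diagonal must be zero")
        object.__setattr__(self, "adjacency", a.astype(np.int8, copy=False))

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def edge_count(self) -> int:
        """Number of unordered interacting pairs."""
        return int(self.adjacency.sum()) // 2

    def edges(self) -> list[tuple[str, str]]:
        """Unordered edges as (u, v) pairs in node order, u before v."""
        r, c = np.nonzero(np.triu(self.adjacency))
        return [(self.nodes[i], self.nodes[j]) for i, j in zip(r, c)]

    def index(self) -> dict[str, int]:
        return {v: i for i, v in enumerate(self.nodes)}


@dataclass(frozen=True)
class ComplexSet:
    """An ordered collection of named protein sets.

    Reference complex catalogues may overlap (the same protein can belong to
    several complexes); algorithm predictions here are partitions, asserted
    via ``partition=True``.  ``background`` holds proteins known to the
    universe but belonging to no complex (e.g. planted background proteins
    of a synthetic data set); for complex sets read from files it is empty,
    so the universe is exactly the union of the members.
    """

    complexes: tuple[tuple[str, frozenset[str]], ...]
    partition: bool = False
    background: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        names = [n for n, _ in self.complexes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate complex names")
        for name, members in self.complexes:
            if not members:
                raise ValueError(f"complex {name!r} is empty")
        if self.partition:
            seen: set[str] = set()
            for name, members in self.complexes:
                if seen & members:
                    raise ValueError(
                        f"partition flag set but complex {name!r} overlaps another"
                    )
                seen |= members
        if self.background & self.member_union:
            raise ValueError("background proteins may not belong to a complex")

    @classmethod
    def from_sets(
        cls,
        sets: Iterable[Iterable[str]],
        names: Iterable[str] | None = None,
        partition: bool = False,
        background: Iterable[str] = (),
    ) -> "ComplexSet":
        sets = [frozenset(s) for s in sets]
        if names is None:
            names = [f"C{i + 1}" for i in range(len(sets))]
        return cls(
            tuple(zip(names, sets)),
            partition=partition,
            background=frozenset(background),
        )

    @property
    def member_union(self) -> frozenset[str]:
        out: set[str] = set()
        for _, members in self.complexes:
            out |= members
        return frozenset(out)

    @property
    def universe(self) -> frozenset[str]:
        return self.member_union | self.background

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(len(m) for _, m in self.complexes)

    def __len__(self) -> int:
        return len(self.complexes)

    def __iter__(self):
        return iter(self.complexes)

    def members(self) -> list[frozenset[str]]:
        return [m for _, m in self.complexes]


def _data_lines(stream: IO[str]) -> Iterable[tuple[int, str]]:
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        yield lineno, line


def read_edge_list(stream: IO[str]) -> PPIGraph:
    """Parse a two-column (or wider) interaction list into a :class:`PPIGraph`.

    The first two whitespace-separated tokens of each line are the protein
    identifiers; any further columns (scores, evidence codes) are ignored.
    Duplicate edges collapse, self-loops are discarded with a logged count,
    and node order follows first appearance.
    """
    nodes: list[str] = []
    index: dict[str, int] = {}
    pairs: set[tuple[int, int]] = set()
    n_self = 0
    saw_line = False
    for lineno, line in _data_lines(stream):
        saw_line = True
        tokens = line.split()
        if len(tokens) < 2:
            raise ValueError(f"line {lineno}: expected at least 2 columns")
        u, v = tokens[0], tokens[1]
        for w in (u, v):
            if w not in index:
                index[w] = len(nodes)
                nodes.append(w)
        if u == v:
            n_self += 1
            continue
        i, j = index[u], index[v]
        pairs.add((min(i, j), max(i, j)))
    if not saw_line:
        raise ValueError("no edges in input")
    if n_self:
        logger.info("dropped %d self-interaction(s)", n_self)
    n = len(nodes)
    adj = np.zeros((n, n), dtype=np.int8)
    if pairs:
        r, c = zip(*pairs)
        adj[list(r), list(c)] = 1
        adj[list(c), list(r)] = 1
    return PPIGraph(tuple(nodes), adj)


def write_edge_list(g: PPIGraph, stream: IO[str], declare_nodes: bool = True) -> None:
    """Emit the graph as a two-column TSV.

    With ``declare_nodes`` (the default) every node is first written as a
    self-pair ``v TAB v``: :func:`read_edge_list` registers the node and then
    discards the self-loop, so reading the file back reproduces the node
    order and adjacency matrix exactly, isolated nodes included.  Without it
    the output is a plain edge list and isolated nodes are lost.
    """
    if declare_nodes:
        for v in g.nodes:
            stream.write(f"{v}\t{v}\n")
    for u, v in g.edges():
        stream.write(f"{u}\t{v}\n")


def read_complexes(stream: IO[str]) -> ComplexSet:
    """Parse a one-complex-per-line file.

    Default dialect: ``name TAB member TAB member...``.  A headerless dialect
    (lines of members only, no name column) is detected when requested via
    lines whose first token re-appears as a member elsewhere is impossible to
    infer reliably, so headerless input is supported explicitly: if every
    line has a single column it is rejected, otherwise the first token is the
    complex name.  Use :func:`read_complexes_headerless` for name-free files.
    """
    complexes: list[tuple[str, frozenset[str]]] = []
    names: set[str] = set()
    saw_line = False
    for lineno, line in _data_lines(stream):
        saw_line = True
        tokens = line.split("\t")
        tokens = [t for t in (tok.strip() for tok in tokens) if t]
        if len(tokens) < 2:
            raise ValueError(f"line {lineno}: complex {tokens[0]!r} has no members")
        name, members = tokens[0], frozenset(tokens[1:])
        if name in names:
            raise ValueError(f"line {lineno}: duplicate complex name {name!r}")
        names.add(name)
        complexes.append((name, members))
    if not saw_line:
        raise ValueError("no complexes in input")
    return ComplexSet(tuple(complexes))


def read_complexes_headerless(stream: IO[str]) -> ComplexSet:
    """Parse a name-free complex file (members only per line); complexes are
    auto-named C1..Ck in line order."""
    complexes: list[tuple[str, frozenset[str]]] = []
    k = 0
    for lineno, line in _data_lines(stream):
        members = frozenset(line.split())
        if not members:
            raise ValueError(f"line {lineno}: empty member list")
        k += 1
        complexes.append((f"C{k}", members))
    if not complexes:
        raise ValueError("no complexes in input")
    return ComplexSet(tuple(complexes))


def write_clusters(cs: ComplexSet, stream: IO[str]) -> None:
    """Write a complex set in the dialect :func:`read_complexes` accepts.

    Members are emitted in sorted order so re-writes are byte-identical.
    Background proteins are not representable in the file dialect and are
    dropped with a log entry.
    """
    if cs.background:
        logger.info(
            "complex file dialect has no background section; %d background "
            "protein(s) not written",
            len(cs.background),
        )
    for name, members in cs.complexes:
        stream.write(name + "\t" + "\t".join(sorted(members)) + "\n")


def write_adjacency_mtx(g: PPIGraph, stream: IO[str]) -> None:
    """Export the adjacency matrix in MatrixMarket coordinate format."""
    from scipy.io import mmwrite
    from scipy.sparse import coo_matrix

    mmwrite(stream, coo_matrix(g.adjacency), field="integer", symmetry="symmetric")


def node_order(ids: Sequence[str]) -> tuple[str, ...]:
    """First-appearance order with duplicates removed (dict preserves order)."""
    return tuple(dict.fromkeys(ids))
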