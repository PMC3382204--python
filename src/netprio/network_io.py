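"""Network and gene-set I/O plus construction of the positive/negative/test partition.

Gene identifiers are opaque strings: no symbol/ID mapping is attempted and
case is preserved verbatim.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionNetwork",
    "GeneSet",
    "GeneSetPartition",
    "NetworkParseError",
    "load_network",
    "write_network",
    "load_gene_set",
    "write_gene_set",
    "build_partition",
]


class NetworkParseError(ValueError):
    """Raised for malformed edge-list / gene-set input, with the line number."""


class InteractionNetwork:
    """An undirected simple graph over gene identifiers.

    Thin wrapper over :class:`networkx.Graph` enforcing simplicity (no
    self-loops, no parallel edges) at construction time.
    """

    def __init__(self, edges: Iterable[tuple[str, str]] = (), nodes: Iterable[str] = ()):
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for a, b in edges:
            if a != b:
                g.add_edge(a, b)
        self._g = g

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "InteractionNetwork":
        net = cls()
        h = nx.Graph()
        h.add_nodes_from(g.nodes())
        h.add_edges_from((a, b) for a, b in g.edges() if a != b)
        net._g = h
        return net

    @property
    def graph(self) -> nx.Graph:
        return self._g

    @property
    def nodes(self) -> set[str]:
        return set(self._g.nodes())

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def edges(self) -> Iterator[tuple[str, str]]:
        return iter(self._g.edges())

    def has_node(self, gene: str) -> bool:
        return self._g.has_node(gene)

    def has_edge(self, a: str, b: str) -> bool:
        return self._g.has_edge(a, b)

    def neighbors(self, gene: str) -> set[str]:
        if not self._g.has_node(gene):
            raise KeyError(f"unknown gene: {gene!r}")
        return set(self._g.neighbors(gene))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionNetwork):
            return NotImplemented
        return self.nodes == other.nodes and set(
            frozenset(e) for e in self.edges()
        ) == set(frozenset(e) for e in other.edges())

    def __repr__(self) -> str:
        return f"InteractionNetwork(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene identifiers."""

    name: str
    members: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(self, "members", frozenset(self.members))

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self.members))


@dataclass(frozen=True)
class GeneSetPartition:
    """Positive / negative / test gene sets, pairwise disjoint, all on-network."""

    positive: GeneSet
    negative: GeneSet
    test: GeneSet

    def __post_init__(self):
        p, n, t = self.positive.members, self.negative.members, self.test.members
        if p & n or p & t or n & t:
            raise ValueError("partition sets must be pairwise disjoint")


def _data_lines(source: IO[str], node_sink: list[str] | None = None) -> Iterator[tuple[int, str]]:
    for lineno, raw in enumerate(source, start=1):
        line = raw.strip()
        if node_sink is not None and line.startswith("#node\t"):
            node_sink.append(line.split("\t", 1)[1])
            continue
        if not line or line.startswith("#"):
            continue
        yield lineno, line


def load_network(source: IO[str], dialect: str = "tsv2col") -> InteractionNetwork:
    """Read an edge list (``tsv2col`` or ``sif`` dialect) into a simple graph.

    Self-loops and duplicate edges are dropped (count logged). Raises
    :class:`NetworkParseError` on malformed lines or empty input.
    """
    if dialect not in ("tsv2col", "sif"):
        raise ValueError(f"unknown dialect: {dialect!r}")
    g = nx.Graph()
    n_loops = 0
    n_dups = 0
    n_lines = 0
    isolated: list[str] = []
    for lineno, line in _data_lines(source, node_sink=isolated):
        n_lines += 1
        fields = line.split("\t") if "\t" in line else line.split()
        if dialect == "tsv2col":
            if len(fields) != 2:
                raise NetworkParseError(
                    f"line {lineno}: expected 2 columns, got {len(fields)}"
                )
            pairs = [(fields[0], fields[1])]
        else:  # sif: source, relation, target(s); a bare node line is allowed
            if len(fields) == 1:
                g.add_node(fields[0])
                continue
            if len(fields) < 3:
                raise NetworkParseError(
                    f"line {lineno}: SIF needs node, relation, node(s); got {len(fields)} fields"
                )
            pairs = [(fields[0], t) for t in fields[2:]]
        for a, b in pairs:
            if a == b:
                n_loops += 1
                g.add_node(a)
                continue
            if g.has_edge(a, b):
                n_dups += 1
                continue
            g.add_edge(a, b)
    g.add_nodes_from(isolated)
    if n_lines == 0 and not isolated:
        raise NetworkParseError("empty network input")
    if n_loops or n_dups:
        logger.info("dropped %d self-loops and %d duplicate edges", n_loops, n_dups)
    return InteractionNetwork.from_networkx(g)


def write_network(network: InteractionNetwork, dest: IO[str]) -> None:
    """Write a 2-column TSV edge list.

    Isolated nodes are emitted as ``#node<TAB>name`` annotation lines, which
    :func:`load_network` restores, so the round trip is exact.
    """
    for a, b in sorted(tuple(sorted(e)) for e in network.edges()):
        dest.write(f"{a}\t{b}\n")
    for node in sorted(network.nodes):
        if network.graph.degree(node) == 0:
            dest.write(f"#node\t{node}\n")


def load_gene_set(source: IO[str], name: str) -> GeneSet:
    """Read a one-identifier-per-line gene list ('#' comments allowed)."""
    seen: list[str] = []
    for _lineno, line in _data_lines(source):
        seen.append(line.split("\t")[0] if "\t" in line else line)
    if not seen:
        raise ValueError(f"gene set {name!r}: empty after parsing")
    members = frozenset(seen)
    n_dups = len(seen) - len(members)
    if n_dups:
        logger.info("gene set %r: dropped %d duplicate identifiers", name, n_dups)
    return GeneSet(name=name, members=members)


def write_gene_set(gene_set: GeneSet, dest: IO[str]) -> None:
    for gene in sorted(gene_set.members):
        dest.write(gene + "\n")


def build_partition(
    network: InteractionNetwork,
    positive: GeneSet,
    de_genes: GeneSet,
    loci_genes: GeneSet,
) -> GeneSetPartition:
    """Construct positive / negative / test sets.

    positive := positive ∩ nodes
    test     := (de_genes ∩ loci_genes ∩ nodes) − positive
    negative := nodes − positive − de_genes

    Differentially expressed genes outside every locus end up unlabeled:
    excluded from negative by definition, and from test for lack of a locus.
    """
    nodes = network.nodes
    pos_on = positive.members & nodes
    if not pos_on:
        raise ValueError("no positive genes present in the network")
    n_pos_off = len(positive.members) - len(pos_on)
    de_on = de_genes.members & nodes
    loci_on = loci_genes.members & nodes
    test = (de_on & loci_on) - pos_on
    negative = nodes - pos_on - de_on
    dropped = (
        n_pos_off
        + len(de_genes.members - nodes)
        + len(loci_genes.members - nodes)
    )
    if dropped:
        logger.info("dropped %d gene-list entries absent from the network", dropped)
    if not test:
        logger.warning("test set is empty")
    return GeneSetPartition(
        positive=GeneSet("positive", frozenset(pos_on)),
        negative=GeneSet("negative", frozenset(negative)),
        test=GeneSet("test", frozenset(test)),
    )
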