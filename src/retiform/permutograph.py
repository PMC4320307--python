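"""The operator-labeled graph on all n! permutations.

Vertices are lexicographic ranks ``1..n!`` (the permutation string is a
vertex attribute); each edge joins two permutations differing by one
negation operator and carries that operator's index as a label.  The graph
is ``(n-1)``-regular, connected, and bipartite by permutation parity.
Edges are stored undirected: the exchanges are bidirectional, direction is
a traversal concern.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field

import networkx as nx

from retiform.errors import BoundError, FormatError, ValidationError
from retiform.permutation_core import (
    Semantics,
    all_permutations,
    apply_negation,
    lex_rank,
)

EXPORT_FORMATS = ("dot", "graphml", "csv")


@dataclass
class Permutograph:
    """Wrapper pairing the labeled graph with its system parameters."""

    n: int
    semantics: Semantics
    graph: nx.Graph = field(repr=False)

    @property
    def size(self) -> int:
        return self.graph.number_of_nodes()

    def permutation_string(self, v: int) -> str:
        return self.graph.nodes[v]["permutation"]


def build_permutograph(n: int, semantics: Semantics = Semantics.VALUE) -> Permutograph:
    """Build the permutograph for valuedness ``n`` (2 <= n <= 7)."""
    if not isinstance(n, int) or isinstance(n, bool) or n < 2 or n > 7:
        raise BoundError(f"permutograph valuedness n={n!r} outside 2..7")
    semantics = Semantics(semantics)
    g = nx.Graph()
    perms = all_permutations(n)
    for rank, p in enumerate(perms, start=1):
        g.add_node(rank, permutation=str(p))
    for rank, p in enumerate(perms, start=1):
        for i in range(1, n):
            other = lex_rank(apply_negation(p, i, semantics))
            if rank < other:
                g.add_edge(rank, other, operator=i)
    return Permutograph(n=n, semantics=semantics, graph=g)


def neighbors(g: Permutograph, v: int) -> dict[int, int]:
    """Map operator index -> neighboring rank for vertex ``v``."""
    if v not in g.graph:
        raise ValidationError(f"vertex {v!r} not in permutograph (1..{g.size})")
    return {
        data["operator"]: u for u, data in sorted(g.graph[v].items())
    }


def _to_dot(g: Permutograph) -> str:
    lines = [f'graph permutograph_n{g.n} {{']
    for v, data in sorted(g.graph.nodes(data=True)):
        lines.append(f'  {v} [label="{data["permutation"]}"];')
    for u, v, data in sorted(g.graph.edges(data=True)):
        lines.append(f'  {u} -- {v} [label="N{data["operator"]}", operator={data["operator"]}];')
    lines.append("}")
    return "\n".join(lines) + "\n"


def _to_csv(g: Permutograph) -> str:
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["source_rank", "target_rank", "operator"])
    for u, v, data in sorted(g.graph.edges(data=True)):
        writer.writerow([u, v, data["operator"]])
    return buf.getvalue()


def export_graph(g: Permutograph, fmt: str, path=None) -> str:
    """Serialize the graph as DOT, GraphML, or an edge-list CSV.

    Returns the serialized text; additionally writes it to ``path`` if given.
    """
    fmt = str(fmt).lower()
    if fmt not in EXPORT_FORMATS:
        raise FormatError(f"unknown format {fmt!r}; choose one of {EXPORT_FORMATS}")
    if fmt == "dot":
        text = _to_dot(g)
    elif fmt == "csv":
        text = _to_csv(g)
    else:
        text = "\n".join(nx.generate_graphml(g.graph)) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def import_graphml(path, n: int, semantics: Semantics = Semantics.VALUE) -> Permutograph:
    """Re-read a GraphML export; vertex ids and attributes are restored exactly."""
    raw = nx.read_graphml(path)
    g = nx.Graph()
    for v, data in raw.nodes(data=True):
        g.add_node(int(v), permutation=data["permutation"])
    for u, v, data in raw.edges(data=True):
        g.add_edge(int(u), int(v), operator=int(data["operator"]))
    return Permutograph(n=n, semantics=Semantics(semantics), graph=g)


def import_csv(path, n: int, semantics: Semantics = Semantics.VALUE) -> Permutograph:
    """Re-read an edge-list CSV export; permutation strings are recomputed from ranks."""
    from retiform.permutation_core import format_permutation, lex_unrank

    g = nx.Graph()
    with open(path) as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            u, v = int(row["source_rank"]), int(row["target_rank"])
            g.add_edge(u, v, operator=int(row["operator"]))
    for v in g.nodes:
        g.nodes[v]["permutation"] = format_permutation(lex_unrank(v, n))
    return Permutograph(n=n, semantics=Semantics(semantics), graph=g)
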