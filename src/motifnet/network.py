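"""Weighted gene co-expression network: loading, neighborhoods, sub-networks
and module calling.

Edges carry partial correlation coefficients; the statistics downstream use
topology only.  A "module" is operationalized as a connected component of a
seed-induced sub-network above a size floor — the reproducible surrogate for
picking densely connected groups off a force-directed layout by eye.
Optional greedy-modularity refinement can split oversized components.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set

import networkx as nx

__all__ = [
    "CoexpressionNetwork",
    "SubNetwork",
    "Module",
    "ModuleSet",
    "read_network",
    "neighborhood",
    "degree_filter",
    "extract_subnetwork",
    "detect_modules",
    "export_graph",
]


@dataclass
class CoexpressionNetwork:
    """Undirected weighted graph of genes; ``pcor`` on every edge."""

    graph: nx.Graph = field(default_factory=nx.Graph)
    pcor_threshold: float = 0.05

    @property
    def nodes(self) -> Set[str]:
        return set(self.graph.nodes)

    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, gene: str) -> int:
        return self.graph.degree[gene]


@dataclass
class SubNetwork:
    """Induced subgraph on a seed gene set; keeps a reference to its parent."""

    parent: CoexpressionNetwork
    graph: nx.Graph

    @property
    def nodes(self) -> Set[str]:
        return set(self.graph.nodes)

    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass(frozen=True)
class Module:
    """A called module: its gene set and a representative-gene label."""

    genes: frozenset
    label: str

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass
class ModuleSet:
    modules: List[Module] = field(default_factory=list)
    min_size: int = 5

    def __len__(self) -> int:
        return len(self.modules)

    def __iter__(self):
        return iter(self.modules)

    def __getitem__(self, i: int) -> Module:
        return self.modules[i]

    def sizes(self) -> List[int]:
        return [m.size for m in self.modules]

    def to_json(self) -> str:
        return json.dumps(
            [
                {"label": m.label, "size": m.size, "genes": sorted(m.genes)}
                for m in self.modules
            ],
            indent=2,
        )


def read_network(path, pcor_threshold: float = 0.05) -> CoexpressionNetwork:
    """Load a 3-column edge list (geneA, geneB, pcor), TSV or whitespace.

    Edges with ``|pcor|`` below the threshold are dropped; duplicate pairs
    collapse keeping the largest ``|pcor|``; self-loops are dropped with a
    warning.  A header line is detected by a non-numeric third field.
    An empty file yields an empty network.
    """
    if pcor_threshold < 0:
        raise ValueError("pcor_threshold must be >= 0")
    g = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            a, b = parts[0], parts[1]
            try:
                pcor = float(parts[2])
            except ValueError:
                if lineno == 1:
                    continue  # header
                raise ValueError(
                    f"{path}:{lineno}: third column {parts[2]!r} is not a number"
                ) from None
            if a == b:
                warnings.warn(f"{path}:{lineno}: self-loop on {a!r} dropped", stacklevel=2)
                continue
            if abs(pcor) < pcor_threshold:
                continue
            if g.has_edge(a, b) and abs(g[a][b]["pcor"]) >= abs(pcor):
                continue
            g.add_edge(a, b, pcor=pcor)
    return CoexpressionNetwork(graph=g, pcor_threshold=pcor_threshold)


def neighborhood(net: CoexpressionNetwork, gene: str) -> Set[str]:
    """The gene *plus* all genes immediately connected to it.

    This is the group on which both motif statistics are computed; note that
    the gene itself is a member.
    """
    if gene not in net.graph:
        raise KeyError(f"gene {gene!r} not in network")
    group = set(net.graph.neighbors(gene))
    group.add(gene)
    return group


def degree_filter(net: CoexpressionNetwork, min_degree: int = 5) -> List[str]:
    """Genes with degree >= ``min_degree``, sorted."""
    if min_degree < 0:
        raise ValueError("min_degree must be >= 0")
    return sorted(g for g, d in net.graph.degree if d >= min_degree)


def extract_subnetwork(net: CoexpressionNetwork, seed_genes: Iterable[str]) -> SubNetwork:
    """Induced subgraph on exactly the seed genes (no neighbor augmentation).

    Seeds absent from the network are dropped with a warning.  An empty seed
    set yields an empty (valid) sub-network.
    """
    seeds = set(seed_genes)
    missing = seeds - net.nodes
    if missing:
        warnings.warn(
            f"{len(missing)} seed gene(s) not in network, dropped", stacklevel=2
        )
    sub = net.graph.subgraph(seeds & net.nodes).copy()
    return SubNetwork(parent=net, graph=sub)


def _representative(graph: nx.Graph, genes: Set[str]) -> str:
    # Highest degree within the sub-network; ties broken lexicographically.
    return min(genes, key=lambda g: (-graph.degree[g], g))


def detect_modules(
    sub: SubNetwork,
    min_size: int = 5,
    refine_above: Optional[int] = None,
) -> ModuleSet:
    """Call modules as connected components of the sub-network.

    Components with fewer than ``min_size`` genes are discarded.  If
    ``refine_above`` is set, components larger than it are split by greedy
    modularity maximization before the size filter (off by default).
    Modules are ordered by size descending, then by label.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    parts: List[Set[str]] = [set(c) for c in nx.connected_components(sub.graph)]
    if refine_above is not None:
        refined: List[Set[str]] = []
        for comp in parts:
            if len(comp) > refine_above:
                communities = nx.community.greedy_modularity_communities(
                    sub.graph.subgraph(comp)
                )
                refined.extend(set(c) for c in communities)
            else:
                refined.append(comp)
        parts = refined
    modules = [
        Module(genes=frozenset(c), label=_representative(sub.graph, c))
        for c in parts
        if len(c) >= min_size
    ]
    modules.sort(key=lambda m: (-m.size, m.label))
    return ModuleSet(modules=modules, min_size=min_size)


def _dot_escape(s: str) -> str:
    return '"' + s.replace('"', r"\"") + '"'


def export_graph(
    sub: SubNetwork,
    path,
    fmt: str = "dot",
    node_attrs: Optional[Dict[str, Dict[str, object]]] = None,
) -> None:
    """Write the sub-network as DOT, GML or a 3-column edge TSV.

    For DOT output a boolean ``has_motif`` node attribute is rendered as a
    red (True) / white (False) fill so the usual module figures can be drawn
    directly with graphviz.
    """
    node_attrs = node_attrs or {}
    if fmt == "dot":
        lines = ["graph subnetwork {", "  node [style=filled];"]
        for gene in sorted(sub.graph.nodes):
            attrs = dict(node_attrs.get(gene, {}))
            color = "red" if attrs.pop("has_motif", False) else "white"
            extra = "".join(f", {k}={_dot_escape(str(v))}" for k, v in attrs.items())
            lines.append(f"  {_dot_escape(gene)} [fillcolor={color}{extra}];")
        for a, b, d in sorted(sub.graph.edges(data=True)):
            lines.append(
                f"  {_dot_escape(a)} -- {_dot_escape(b)} [weight={d.get('pcor', 1.0):.6g}];"
            )
        lines.append("}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
    elif fmt == "gml":
        g = sub.graph.copy()
        for gene, attrs in node_attrs.items():
            if gene in g:
                for k, v in attrs.items():
                    g.nodes[gene][k] = int(v) if isinstance(v, bool) else v
        nx.write_gml(g, str(path))
    elif fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("geneA\tgeneB\tpcor\n")
            for a, b, d in sorted(sub.graph.edges(data=True)):
                fh.write(f"{a}\t{b}\t{d.get('pcor', 1.0):.6g}\n")
    else:
        raise ValueError(f"unknown export format {fmt!r} (use dot, gml or tsv)")
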