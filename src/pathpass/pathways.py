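"""Pathway definitions: parsing, filtering, and fully connected networks.

A pathway is a set of genes plus the undirected interactions between them.
For single-sample scoring every pathway is expanded into the complete graph
on its expressed genes: the real interactions form the *attention* edge set
and the artificially added pairs form the *background* edge set.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from lxml import etree

logger = logging.getLogger(__name__)

#: An undirected edge in canonical form (lexicographically sorted pair).
Edge = tuple[str, str]


def canonical_edge(a: str, b: str) -> Edge:
    """Return the unordered gene pair in canonical (sorted) order."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class Pathway:
    """A gene set with its undirected interaction edges.

    Invariants: every edge endpoint is a member gene, edges are canonical
    unordered pairs, and there are no self-loops.
    """

    id: str
    name: str
    genes: frozenset[str]
    edges: frozenset[Edge]

    def __post_init__(self) -> None:
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"pathway {self.id}: self-loop edge {a!r}")
            if (a, b) != canonical_edge(a, b):
                raise ValueError(f"pathway {self.id}: non-canonical edge ({a!r}, {b!r})")
            if a not in self.genes or b not in self.genes:
                raise ValueError(
                    f"pathway {self.id}: edge ({a!r}, {b!r}) has endpoint outside gene set"
                )

    @property
    def sorted_genes(self) -> list[str]:
        return sorted(self.genes)

    @property
    def sorted_edges(self) -> list[Edge]:
        return sorted(self.edges)


@dataclass(frozen=True)
class FullyConnectedPathwayNetwork:
    """Complete undirected graph on a pathway's expressed genes.

    ``edge_records`` lists every unordered gene pair in lexicographic order
    with a boolean attention flag (True for a real pathway edge, False for
    an artificially added background edge).
    """

    pathway_id: str
    nodes: tuple[str, ...]
    edge_records: tuple[tuple[Edge, bool], ...]

    @property
    def m_attention(self) -> int:
        return sum(1 for _, flag in self.edge_records if flag)

    @property
    def n_background(self) -> int:
        return len(self.edge_records) - self.m_attention

    @property
    def edges(self) -> list[Edge]:
        return [pair for pair, _ in self.edge_records]

    @property
    def attention_flags(self) -> list[bool]:
        return [flag for _, flag in self.edge_records]


@dataclass(frozen=True)
class GeneUniverse:
    """Union of member genes over all retained pathways, in sorted order."""

    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene universe contains duplicates")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)


class PathwayParseError(ValueError):
    """Raised when a GMT / edge-list / KGML file is malformed."""


def parse_pathway_files(gmt_path: str | Path, edges_path: str | Path) -> list[Pathway]:
    """Parse a GMT gene-set file plus a 3-column pathway edge-list TSV.

    GMT lines are ``pathway_id<TAB>name<TAB>gene1<TAB>gene2...``; edge lines
    are ``pathway_id<TAB>geneA<TAB>geneB`` with no header. Duplicate and
    reversed pairs collapse to one undirected edge; self-loops are dropped
    with a warning; edge endpoints missing from the GMT gene list are added
    to the pathway's gene set with a warning.
    """
    gmt_path, edges_path = Path(gmt_path), Path(edges_path)
    order: list[str] = []
    names: dict[str, str] = {}
    genes: dict[str, set[str]] = {}

    with gmt_path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise PathwayParseError(
                    f"{gmt_path}:{lineno}: expected at least 3 tab-separated fields"
                )
            pid, name, members = fields[0], fields[1], fields[2:]
            if pid in names:
                raise PathwayParseError(f"{gmt_path}:{lineno}: duplicate pathway id {pid!r}")
            if not all(members):
                raise PathwayParseError(f"{gmt_path}:{lineno}: empty gene field")
            order.append(pid)
            names[pid] = name
            genes[pid] = set(members)

    edges: dict[str, set[Edge]] = {pid: set() for pid in order}
    with edges_path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise PathwayParseError(
                    f"{edges_path}:{lineno}: expected 3 tab-separated fields"
                )
            pid, a, b = fields
            if pid not in names:
                raise PathwayParseError(
                    f"{edges_path}:{lineno}: edge references unknown pathway id {pid!r}"
                )
            if not a or not b:
                raise PathwayParseError(f"{edges_path}:{lineno}: empty gene field")
            if a == b:
                logger.warning("%s:%d: dropping self-loop edge %s-%s in %s",
                               edges_path, lineno, a, b, pid)
                continue
            for g in (a, b):
                if g not in genes[pid]:
                    logger.warning(
                        "%s:%d: edge endpoint %s absent from GMT gene list of %s; adding",
                        edges_path, lineno, g, pid)
                    genes[pid].add(g)
            edges[pid].add(canonical_edge(a, b))

    return [
        Pathway(id=pid, name=names[pid], genes=frozenset(genes[pid]),
                edges=frozenset(edges[pid]))
        for pid in order
    ]


def _kgml_entry_genes(entry: etree._Element) -> list[str]:
    """Gene identifiers of a KGML gene entry, namespace prefix stripped."""
    tokens = (entry.get("name") or "").split()
    return [tok.split(":", 1)[-1] for tok in tokens if tok]


def parse_kgml_directory(dir_path: str | Path) -> list[Pathway]:
    """Parse every KEGG KGML XML file in a directory into Pathways.

    Gene entries become nodes; ``relation`` elements between two gene
    entries become undirected edges (directed/duplicate relations collapse).
    Group, compound and map entries are ignored. Files are processed in
    sorted name order for determinism.
    """
    dir_path = Path(dir_path)
    pathways: list[Pathway] = []
    files = sorted(p for p in dir_path.iterdir()
                   if p.suffix.lower() in {".xml", ".kgml"})
    for path in files:
        try:
            tree = etree.parse(str(path))
        except (etree.XMLSyntaxError, OSError) as exc:
            raise PathwayParseError(f"cannot parse KGML file {path}: {exc}") from exc
        root = tree.getroot()
        pid = (root.get("name") or path.stem).split(":", 1)[-1]
        name = root.get("title") or pid

        entry_genes: dict[str, list[str]] = {}
        genes: set[str] = set()
        for entry in root.iter("entry"):
            if entry.get("type") != "gene":
                continue
            toks = _kgml_entry_genes(entry)
            entry_genes[entry.get("id")] = toks
            genes.update(toks)

        edges: set[Edge] = set()
        for rel in root.iter("relation"):
            g1 = entry_genes.get(rel.get("entry1"))
            g2 = entry_genes.get(rel.get("entry2"))
            if not g1 or not g2:
                continue  # relation touches a non-gene entry
            for a, b in itertools.product(g1, g2):
                if a != b:
                    edges.add(canonical_edge(a, b))

        pathways.append(Pathway(id=pid, name=name, genes=frozenset(genes),
                                edges=frozenset(edges)))
    return pathways


def filter_pathways(pathways: Sequence[Pathway],
                    expressed_genes: Iterable[str]) -> list[Pathway]:
    """Restrict pathways to expressed genes and drop near-empty pathways.

    Genes absent from the expression profile are removed along with their
    incident edges; pathways left with one edge or fewer are excluded.
    Order of retained pathways is preserved. Idempotent.
    """
    expressed = set(expressed_genes)
    kept: list[Pathway] = []
    for pw in pathways:
        genes = pw.genes & expressed
        edges = frozenset(e for e in pw.edges if e[0] in genes and e[1] in genes)
        if len(edges) <= 1:
            logger.info("pathway %s excluded after filtering (%d edge(s) survive)",
                        pw.id, len(edges))
            continue
        kept.append(Pathway(id=pw.id, name=pw.name, genes=frozenset(genes), edges=edges))
    return kept


def build_fully_connected(pathway: Pathway) -> FullyConnectedPathwayNetwork:
    """Expand a filtered pathway into its complete graph with attention flags."""
    if len(pathway.genes) < 2:
        raise ValueError(f"pathway {pathway.id}: fewer than 2 genes")
    nodes = tuple(sorted(pathway.genes))
    records = tuple(
        ((a, b), (a, b) in pathway.edges)
        for a, b in itertools.combinations(nodes, 2)
    )
    return FullyConnectedPathwayNetwork(pathway_id=pathway.id, nodes=nodes,
                                        edge_records=records)


def gene_universe(pathways: Sequence[Pathway]) -> GeneUniverse:
    """Union of member genes over all retained pathways, sorted."""
    if not pathways:
        raise ValueError("cannot build a gene universe from an empty pathway list")
    union: set[str] = set()
    for pw in pathways:
        union |= pw.genes
    return GeneUniverse(genes=tuple(sorted(union)))


def pathways_to_json(pathways: Sequence[Pathway]) -> str:
    """Serialize pathways to a deterministic JSON document (provenance)."""
    doc = [
        {"id": pw.id, "name": pw.name, "genes": pw.sorted_genes,
         "edges": [list(e) for e in pw.sorted_edges]}
        for pw in pathways
    ]
    return json.dumps(doc, indent=1, sort_keys=True)


def pathways_from_json(text: str) -> list[Pathway]:
    doc = json.loads(text)
    return [
        Pathway(id=d["id"], name=d["name"], genes=frozenset(d["genes"]),
                edges=frozenset(canonical_edge(a, b) for a, b in d["edges"]))
        for d in doc
    ]
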