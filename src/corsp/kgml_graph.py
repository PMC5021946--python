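"""Reconstruction of metabolic pathways as undirected compound–enzyme graphs.

KEGG distributes each pathway map as a KGML (KEGG Markup Language) XML file
listing *entries* (compounds, gene products / KEGG Orthology groups, links to
other maps) and *reactions* (substrates, products, and the catalysing
entries).  For subpathway analysis each pathway is rebuilt as an undirected
bipartite graph: map-link entries are dropped, every substrate compound of a
reaction is joined to each of the reaction's enzyme nodes, and every enzyme
node is joined to each product compound.  Enzyme nodes are labelled by KO
(KEGG Orthology) identifiers so that genes can be joined to the graph through
a gene→KO annotation table.  Topological distance between nodes is the
unweighted shortest-path hop count (breadth-first search).
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import networkx as nx
from lxml import etree

logger = logging.getLogger(__name__)

#: Sentinel distance for node pairs in different connected components.
UNREACHABLE = None

# KGML "type" attribute → entry kind used here.
_ENTRY_KINDS = {
    "compound": "compound",
    "gene": "enzyme",
    "ortholog": "enzyme",
    "enzyme": "enzyme",
    "map": "map",
}

_ID_PREFIXES = ("cpd:", "ko:", "ec:", "gl:", "dr:", "path:")


class KgmlParseError(ValueError):
    """Malformed KGML input (XML syntax or missing required attributes)."""


class KgmlValidationError(ValueError):
    """Structurally valid XML whose content violates KGML expectations."""


@dataclass(frozen=True)
class Entry:
    entry_id: str
    kind: str  # compound | enzyme | map | other
    kegg_ids: tuple[str, ...]


@dataclass(frozen=True)
class Reaction:
    substrates: tuple[str, ...]  # entry ids
    products: tuple[str, ...]
    enzymes: tuple[str, ...]


@dataclass
class PathwayDefinition:
    """Raw parse product of one KGML file, prior to graph reconstruction."""

    pathway_id: str
    title: str
    entries: list[Entry] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)

    def validate(self) -> None:
        ids = [e.entry_id for e in self.entries]
        if len(ids) != len(set(ids)):
            raise KgmlValidationError(
                f"{self.pathway_id}: duplicate entry ids in pathway definition"
            )
        declared = set(ids)
        for rx in self.reactions:
            for ref in (*rx.substrates, *rx.products, *rx.enzymes):
                if ref not in declared:
                    raise KgmlValidationError(
                        f"{self.pathway_id}: reaction references undeclared "
                        f"entry id {ref!r}"
                    )


def _strip_prefix(name: str) -> str:
    for p in _ID_PREFIXES:
        if name.startswith(p):
            return name[len(p):]
    return name


def parse_kgml(xml_text: str | bytes) -> PathwayDefinition:
    """Parse one KGML document into a :class:`PathwayDefinition`.

    Entry kinds are classified from the KGML ``type`` attribute (``compound``,
    ``gene``/``ortholog``/``enzyme`` → enzyme, ``map``; anything else →
    ``other``).  Reaction enzymes are resolved from the reaction ``id``
    attribute (which in KGML names the catalysing entry) plus any entry whose
    ``reaction`` attribute matches the reaction name.

    Raises
    ------
    KgmlParseError
        On malformed XML (the message carries the reported line number) or a
        missing pathway ``name`` attribute.
    KgmlValidationError
        If a reaction references an undeclared entry id.
    """
    if isinstance(xml_text, str):
        xml_text = xml_text.encode()
    try:
        # KGML ships a DTD reference; never fetch it.
        parser = etree.XMLParser(load_dtd=False, no_network=True, resolve_entities=False)
        root = etree.parse(io.BytesIO(xml_text), parser).getroot()
    except etree.XMLSyntaxError as exc:
        raise KgmlParseError(f"malformed KGML XML: {exc}") from exc
    if root.tag != "pathway":
        raise KgmlParseError(f"expected <pathway> root element, got <{root.tag}>")
    pathway_id = root.get("name")
    if not pathway_id:
        raise KgmlParseError("pathway element lacks required 'name' attribute")
    defn = PathwayDefinition(pathway_id=pathway_id, title=root.get("title", ""))

    entry_reaction_names: dict[str, set[str]] = {}
    for el in root.iter("entry"):
        eid = el.get("id")
        if eid is None:
            raise KgmlParseError("entry element lacks required 'id' attribute")
        kind = _ENTRY_KINDS.get(el.get("type", ""), "other")
        names = tuple(_strip_prefix(n) for n in (el.get("name") or "").split() if n)
        defn.entries.append(Entry(entry_id=eid, kind=kind, kegg_ids=names))
        rx_attr = el.get("reaction")
        if rx_attr:
            entry_reaction_names[eid] = set(rx_attr.split())

    enzyme_ids = {e.entry_id for e in defn.entries if e.kind == "enzyme"}
    for el in root.iter("reaction"):
        substrates = tuple(s.get("id") for s in el.iter("substrate"))
        products = tuple(p.get("id") for p in el.iter("product"))
        enzymes: list[str] = []
        rid = el.get("id")
        if rid in enzyme_ids:
            enzymes.append(rid)
        rname = el.get("name", "")
        rnames = set(rname.split())
        for eid, attached in entry_reaction_names.items():
            if eid in enzyme_ids and eid not in enzymes and attached & rnames:
                enzymes.append(eid)
        defn.reactions.append(
            Reaction(substrates=substrates, products=products, enzymes=tuple(enzymes))
        )
    defn.validate()
    return defn


def serialize_kgml(defn: PathwayDefinition) -> str:
    """Serialize a :class:`PathwayDefinition` back to a KGML document.

    Round-trips through :func:`parse_kgml`: enzymes are emitted via the
    entry ``reaction`` attribute convention.
    """
    root = etree.Element("pathway", name=defn.pathway_id, title=defn.title)
    kind_to_type = {"compound": "compound", "enzyme": "ortholog", "map": "map",
                    "other": "other"}
    prefix = {"compound": "cpd:", "enzyme": "ko:", "map": "path:", "other": ""}
    rx_name = {}
    for k, rx in enumerate(defn.reactions):
        rx_name[k] = f"rn:R{k + 1:05d}"
    enzyme_rx: dict[str, list[str]] = {}
    for k, rx in enumerate(defn.reactions):
        for eid in rx.enzymes:
            enzyme_rx.setdefault(eid, []).append(rx_name[k])
    for e in defn.entries:
        el = etree.SubElement(
            root, "entry", id=e.entry_id, type=kind_to_type[e.kind],
            name=" ".join(prefix[e.kind] + i for i in e.kegg_ids),
        )
        if e.entry_id in enzyme_rx:
            el.set("reaction", " ".join(enzyme_rx[e.entry_id]))
    for k, rx in enumerate(defn.reactions):
        el = etree.SubElement(root, "reaction", id=rx.enzymes[0] if rx.enzymes else "",
                              name=rx_name[k], type="reversible")
        for sid in rx.substrates:
            etree.SubElement(el, "substrate", id=sid)
        for pid in rx.products:
            etree.SubElement(el, "product", id=pid)
    return etree.tostring(root, pretty_print=True, xml_declaration=True,
                          encoding="UTF-8").decode()


class PathwayGraph:
    """Undirected bipartite compound–enzyme graph for one pathway.

    Thin wrapper around :class:`networkx.Graph`.  Nodes are keyed by the
    sorted ``|``-joined KEGG ids of the collapsed entries and carry
    ``node_type`` (``compound``/``enzyme``) and ``kegg_ids`` attributes.
    Entries sharing the same KEGG id set are collapsed to a single node so
    that distances reflect chemistry rather than drawing layout.
    """

    def __init__(self, pathway_id: str, graph: nx.Graph | None = None):
        self.pathway_id = pathway_id
        self.graph = graph if graph is not None else nx.Graph()

    # -- construction -----------------------------------------------------

    def add_node(self, node_type: str, kegg_ids: tuple[str, ...]) -> str:
        node_id = "|".join(sorted(kegg_ids))
        if node_id not in self.graph:
            self.graph.add_node(node_id, node_type=node_type,
                                kegg_ids=tuple(sorted(kegg_ids)))
        return node_id

    # -- queries ----------------------------------------------------------

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges

    def node_type(self, node_id: str) -> str:
        return self.graph.nodes[node_id]["node_type"]

    def kegg_ids(self, node_id: str) -> tuple[str, ...]:
        return self.graph.nodes[node_id]["kegg_ids"]

    def compound_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True)
                if d["node_type"] == "compound"]

    def enzyme_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True)
                if d["node_type"] == "enzyme"]

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def __repr__(self) -> str:  # pragma: no cover
        return (f"PathwayGraph({self.pathway_id!r}, "
                f"{len(self)} nodes, {self.graph.number_of_edges()} edges)")

    # -- export -----------------------------------------------------------

    def to_edgelist_tsv(self) -> str:
        lines = ["node_id_1\tnode_id_2"]
        for u, v in sorted(map(lambda e: tuple(sorted(e)), self.graph.edges)):
            lines.append(f"{u}\t{v}")
        return "\n".join(lines) + "\n"

    def to_graphml(self, path) -> None:
        g = nx.Graph(self.graph)
        for _, data in g.nodes(data=True):
            data["kegg_ids"] = " ".join(data["kegg_ids"])
        nx.write_graphml(g, path)


def reconstruct_graph(defn: PathwayDefinition) -> PathwayGraph:
    """Rebuild one pathway definition as an undirected compound–enzyme graph.

    Map-link entries are dropped.  For every reaction, each substrate compound
    is connected to each catalysing enzyme node and each enzyme node to each
    product compound; a reaction with no resolvable enzyme contributes no
    edges (logged) since compound–compound shortcuts are never invented.
    """
    pg = PathwayGraph(defn.pathway_id)
    by_id: dict[str, Entry] = {e.entry_id: e for e in defn.entries}
    node_of: dict[str, str] = {}
    for e in defn.entries:
        if e.kind in ("compound", "enzyme") and e.kegg_ids:
            node_of[e.entry_id] = pg.add_node(e.kind, e.kegg_ids)
    for rx in defn.reactions:
        enzymes = [node_of[i] for i in rx.enzymes
                   if i in node_of and by_id[i].kind == "enzyme"]
        if not enzymes:
            logger.warning("%s: reaction with no enzyme entry skipped",
                           defn.pathway_id)
            continue
        for sid in rx.substrates:
            if sid in node_of and by_id[sid].kind == "compound":
                for enz in enzymes:
                    pg.graph.add_edge(node_of[sid], enz)
        for pid in rx.products:
            if pid in node_of and by_id[pid].kind == "compound":
                for enz in enzymes:
                    pg.graph.add_edge(node_of[pid], enz)
    return pg


class DistanceTable:
    """All-pairs unweighted shortest-path hop counts for one pathway graph.

    ``distance(i, j)`` returns an ``int`` or :data:`UNREACHABLE` (``None``)
    for pairs in different components.  Symmetric with zero diagonal.
    """

    def __init__(self, lengths: dict[str, dict[str, int]]):
        self._lengths = lengths

    def distance(self, i: str, j: str):
        if i not in self._lengths or j not in self._lengths:
            raise KeyError(f"unknown node id: {i if i not in self._lengths else j}")
        return self._lengths[i].get(j, UNREACHABLE)

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._lengths

    def items(self):
        return self._lengths.items()


def shortest_path_lengths(graph: PathwayGraph) -> DistanceTable:
    """BFS all-pairs hop distances; disconnected pairs are UNREACHABLE."""
    lengths = {src: dict(d) for src, d in
               nx.all_pairs_shortest_path_length(graph.graph)}
    return DistanceTable(lengths)


def shortest_path_nodes(graph: PathwayGraph, i: str, j: str) -> set[str]:
    """Union of the node sets of ALL shortest paths between ``i`` and ``j``.

    Includes both endpoints.  When several shortest paths tie, every node on
    any of them is returned (a node ``v`` lies on some shortest path iff
    ``d(i,v) + d(v,j) == d(i,j)``), so the result needs no tie-breaking and is
    deterministic.  An unreachable pair yields the empty set (distinct from
    ``{i, j}``); unknown node ids raise ``KeyError``.
    """
    g = graph.graph
    if i not in g or j not in g:
        raise KeyError(f"unknown node id: {i if i not in g else j}")
    if i == j:
        return {i}
    di = nx.single_source_shortest_path_length(g, i)
    if j not in di:
        return set()
    dj = nx.single_source_shortest_path_length(g, j)
    d = di[j]
    return {v for v, dv in di.items() if v in dj and dv + dj[v] == d}
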