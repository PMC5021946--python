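"""CorSP scoring and subpathway extraction.

For every pathway containing nodes of interest, each unordered pair of
interest nodes gets a CorSP score combining its expression correlation
``c_ij`` (Pearson, from the molecule profiles mapped to the nodes) with its
topological distance ``d_ij`` (BFS hop count in the reconstructed pathway
graph).  The default functional form is

    CorSP_ij = beta * c_ij / d_ij        (beta = 10 by default)

which is strictly increasing in ``c_ij`` and strictly decreasing in ``d_ij``;
any user-supplied form must satisfy the same monotonicity contract.  A global
threshold ``m`` is chosen so that a configured fraction (default 70%) of all
pair scores, pooled over the whole pathway collection, passes it strictly.
Pairs scoring above ``m`` are merged into one node set together with every
node lying on any of their shortest paths ("lenient distance" agglomeration);
merged sets of at least ``s`` nodes (default 5) become subpathway regions.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .interest_screen import InterestSet, pairwise_pcc
from .kgml_graph import (PathwayGraph, UNREACHABLE, shortest_path_lengths,
                         shortest_path_nodes)

logger = logging.getLogger(__name__)

AUTO = "auto"


@dataclass(frozen=True)
class NodeOfInterest:
    pathway_id: str
    node_id: str
    node_type: str  # compound | enzyme
    mapped_molecules: tuple[str, ...]  # interest metabolite or gene ids


@dataclass
class CorsPair:
    node_i: str
    node_j: str
    c_ij: float
    d_ij: int | None
    score: float  # NaN when d_ij is UNREACHABLE
    beta: float


@dataclass
class SubpathwayConfig:
    """Tunable knobs of the subpathway location step.

    ``m`` may be a number or :data:`AUTO`, in which case the threshold is the
    largest observed score value with at least ``pass_fraction`` of all
    pooled scores strictly above it.
    """

    beta: float = 10.0
    m: float | str = AUTO
    pass_fraction: float = 0.70
    s: int = 5
    corr_aggregation: str = "max_abs"  # or "mean"
    use_abs_corr: bool = False
    score_fn: Callable[[float, int, float], float] | None = None

    def __post_init__(self):
        if not (0 < self.pass_fraction < 1):
            raise ValueError("pass_fraction must lie in (0, 1)")
        if self.s < 1:
            raise ValueError("s must be >= 1")
        if self.beta <= 0:
            raise ValueError("beta must be > 0")


@dataclass
class Subpathway:
    subpathway_id: str
    pathway_id: str
    node_ids: frozenset[str]
    interest_node_ids: frozenset[str]
    mean_pcc: float | None = None

    def __len__(self) -> int:
        return len(self.node_ids)


# ---------------------------------------------------------------------------
# Mapping interest molecules onto graph nodes
# ---------------------------------------------------------------------------

def map_interest_to_nodes(graph: PathwayGraph, interest: InterestSet,
                          gene_to_ko: Mapping[str, str | Iterable[str]]
                          ) -> list[NodeOfInterest]:
    """Nodes of interest for one pathway graph.

    A compound node is of interest iff one of its compound ids is an interest
    metabolite; an enzyme node iff any interest gene maps (via ``gene_to_ko``)
    to one of its KO ids.  Nodes may carry several mapped molecules.
    """
    ko_to_genes: dict[str, set[str]] = {}
    for g in interest.genes:
        kos = gene_to_ko.get(g)
        if kos is None:
            continue
        if isinstance(kos, str):
            kos = [kos]
        for ko in kos:
            ko_to_genes.setdefault(ko, set()).add(g)
    out: list[NodeOfInterest] = []
    for node_id in sorted(graph.nodes):
        ntype = graph.node_type(node_id)
        ids = graph.kegg_ids(node_id)
        if ntype == "compound":
            mols = sorted(set(ids) & interest.metabolites)
        else:
            mols = sorted(set().union(*(ko_to_genes.get(k, set()) for k in ids))
                          if ids else set())
        if mols:
            out.append(NodeOfInterest(pathway_id=graph.pathway_id,
                                      node_id=node_id, node_type=ntype,
                                      mapped_molecules=tuple(mols)))
    return out


def node_pair_pcc(node_i: NodeOfInterest, node_j: NodeOfInterest,
                  profiles: pd.DataFrame, aggregation: str = "max_abs",
                  min_periods: int = 5) -> float:
    """Correlation between two interest nodes' expression profiles.

    ``profiles`` holds one row per molecule (metabolites and genes stacked).
    Single-molecule nodes use their molecules' Pcc directly; multi-molecule
    nodes aggregate over all cross-pairs by the configured rule:
    ``max_abs`` (signed value of the cross-pair with maximum |Pcc|, default)
    or ``mean``.  NaN when no cross-pair is computable.
    """
    rows_i = profiles.loc[list(node_i.mapped_molecules)].to_numpy(dtype=float)
    rows_j = profiles.loc[list(node_j.mapped_molecules)].to_numpy(dtype=float)
    r = pairwise_pcc(rows_i, rows_j, min_periods=min_periods).ravel()
    r = r[np.isfinite(r)]
    if len(r) == 0:
        return float("nan")
    if aggregation == "max_abs":
        return float(r[np.argmax(np.abs(r))])
    if aggregation == "mean":
        return float(np.mean(r))
    raise ValueError(f"unknown aggregation rule {aggregation!r}")


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def corsp_score(c_ij: float, d_ij: int | None, beta: float = 10.0,
                score_fn: Callable[[float, int, float], float] | None = None
                ) -> float:
    """CorSP pair score; NaN for unreachable pairs (they never cluster).

    Default form ``beta * c_ij / d_ij``.  A custom ``score_fn(c, d, beta)``
    must be strictly increasing in ``c`` and strictly decreasing in ``d``.
    """
    if d_ij is UNREACHABLE:
        return float("nan")
    if d_ij < 1:
        raise ValueError("pair distance must be >= 1 for distinct nodes")
    if score_fn is not None:
        return float(score_fn(c_ij, d_ij, beta))
    return beta * c_ij / d_ij


def score_pathway_pairs(graph: PathwayGraph,
                        interest_nodes: Sequence[NodeOfInterest],
                        profiles: pd.DataFrame,
                        config: SubpathwayConfig,
                        min_periods: int = 5) -> list[CorsPair]:
    """All unordered interest-node pairs of one pathway with c, d and score."""
    dist = shortest_path_lengths(graph)
    pairs: list[CorsPair] = []
    for ni, nj in itertools.combinations(interest_nodes, 2):
        c = node_pair_pcc(ni, nj, profiles,
                          aggregation=config.corr_aggregation,
                          min_periods=min_periods)
        if not np.isfinite(c):
            logger.warning("%s: pair (%s, %s) has no computable correlation; "
                           "excluded", graph.pathway_id, ni.node_id, nj.node_id)
            continue
        c_eff = abs(c) if config.use_abs_corr else c
        d = dist.distance(ni.node_id, nj.node_id)
        score = corsp_score(c_eff, d, beta=config.beta,
                            score_fn=config.score_fn)
        pairs.append(CorsPair(node_i=ni.node_id, node_j=nj.node_id,
                              c_ij=c, d_ij=d, score=score, beta=config.beta))
    return pairs


def select_threshold_m(scores: Iterable[float],
                       pass_fraction: float = 0.70) -> float:
    """Threshold m: the largest observed score with >= ``pass_fraction`` of
    all scores strictly greater than it.

    Scores must be pooled globally across the whole pathway collection.  The
    strict inequality matches the clustering rule (pairs merge when their
    score exceeds m).  If even the minimum score fails (e.g. all scores
    equal), the largest representable value below the minimum is returned so
    the passing fraction is 1.
    """
    arr = np.asarray([s for s in scores if np.isfinite(s)], dtype=float)
    if arr.size == 0:
        raise ValueError("no finite CorSP scores to pool; cannot select m")
    arr.sort()
    n = arr.size
    for v in np.unique(arr)[::-1]:
        n_greater = n - np.searchsorted(arr, v, side="right")
        if n_greater / n >= pass_fraction:
            return float(v)
    return float(np.nextafter(arr[0], -np.inf))


# ---------------------------------------------------------------------------
# Agglomeration and extraction
# ---------------------------------------------------------------------------

class _UnionFind:
    def __init__(self, items: Iterable[str]):
        self.parent = {x: x for x in items}

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def cluster_interest_nodes(graph: PathwayGraph, pairs: Sequence[CorsPair],
                           m: float) -> list[set[str]]:
    """Merge interest nodes whose CorSP score strictly exceeds ``m``.

    Disjoint-set semantics: each passing pair unions its two interest nodes
    and injects every node on any of their shortest paths into the merged
    set.  The fixpoint is order-independent, so no iteration order matters;
    interest nodes touched by no passing pair remain singleton sets.
    """
    interest_ids = sorted({n for p in pairs for n in (p.node_i, p.node_j)})
    uf = _UnionFind(interest_ids)
    injected: list[tuple[str, set[str]]] = []
    for p in pairs:
        if np.isfinite(p.score) and p.score > m:
            uf.union(p.node_i, p.node_j)
            injected.append((p.node_i,
                             shortest_path_nodes(graph, p.node_i, p.node_j)))
    members: dict[str, set[str]] = {}
    for nid in interest_ids:
        members.setdefault(uf.find(nid), set()).add(nid)
    for anchor, path_nodes in injected:
        members[uf.find(anchor)] |= path_nodes
    return [members[root] for root in sorted(members)]


def extract_subpathways(graph: PathwayGraph, node_sets: Sequence[set[str]],
                        s: int = 5,
                        interest_node_ids: Iterable[str] = ()
                        ) -> list[Subpathway]:
    """Keep node sets with >= ``s`` nodes as subpathway regions.

    Region ids are ``<pathway_id>_<k>`` with k assigned by descending node
    count, ties broken by the lexicographically smallest member node id.
    Every extracted region's induced subgraph is connected (guaranteed by the
    shortest-path injection; asserted).
    """
    interest_ids = set(interest_node_ids)
    surviving = [ns for ns in node_sets if len(ns) >= s]
    surviving.sort(key=lambda ns: (-len(ns), min(ns)))
    out = []
    for k, ns in enumerate(surviving, start=1):
        sub = graph.graph.subgraph(ns)
        assert nx.is_connected(sub), "extracted region must be connected"
        out.append(Subpathway(
            subpathway_id=f"{graph.pathway_id}_{k}",
            pathway_id=graph.pathway_id,
            node_ids=frozenset(ns),
            interest_node_ids=frozenset(ns & interest_ids),
        ))
    return out


def mean_region_pcc(sub: Subpathway,
                    interest_nodes: Mapping[str, NodeOfInterest],
                    profiles: pd.DataFrame,
                    min_periods: int = 5) -> float | None:
    """Average Pcc over all unordered pairs of interest molecules mapped to
    the region's nodes; None when fewer than two molecules are mapped."""
    mols = sorted({m for nid in sub.interest_node_ids
                   for m in interest_nodes[nid].mapped_molecules})
    if len(mols) < 2:
        return None
    x = profiles.loc[mols].to_numpy(dtype=float)
    r = pairwise_pcc(x, x, min_periods=min_periods)
    iu = np.triu_indices(len(mols), k=1)
    vals = r[iu]
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        return None
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Collection-level driver
# ---------------------------------------------------------------------------

@dataclass
class CorspResult:
    subpathways: list[Subpathway]
    m: float
    pairs_by_pathway: dict[str, list[CorsPair]]
    interest_nodes_by_pathway: dict[str, list[NodeOfInterest]]

    @property
    def interest_nodes(self) -> dict[str, NodeOfInterest]:
        return {n.node_id: n
                for nodes in self.interest_nodes_by_pathway.values()
                for n in nodes}


def identify_subpathways(graphs: Sequence[PathwayGraph],
                         interest: InterestSet,
                         profiles: pd.DataFrame,
                         gene_to_ko: Mapping[str, str | Iterable[str]],
                         config: SubpathwayConfig | None = None,
                         min_periods: int = 5) -> CorspResult:
    """Run the full subpathway location step over a pathway collection.

    Scores all interest-node pairs per pathway, pools the finite scores
    globally to select m (unless a fixed m is configured), agglomerates, and
    extracts regions of at least ``config.s`` nodes with their mean regional
    Pcc.  Pathways without interest nodes are skipped (logged).
    """
    config = config or SubpathwayConfig()
    pairs_by_pw: dict[str, list[CorsPair]] = {}
    nodes_by_pw: dict[str, list[NodeOfInterest]] = {}
    for g in graphs:
        nodes = map_interest_to_nodes(g, interest, gene_to_ko)
        if not nodes:
            logger.info("%s: no interest nodes; skipped", g.pathway_id)
            continue
        nodes_by_pw[g.pathway_id] = nodes
        pairs_by_pw[g.pathway_id] = score_pathway_pairs(
            g, nodes, profiles, config, min_periods=min_periods)
    pooled = [p.score for pl in pairs_by_pw.values() for p in pl
              if np.isfinite(p.score)]
    if config.m == AUTO:
        m = select_threshold_m(pooled, config.pass_fraction)
    else:
        m = float(config.m)
    graph_by_id = {g.pathway_id: g for g in graphs}
    all_subs: list[Subpathway] = []
    node_lookup: dict[str, NodeOfInterest] = {}
    for pw_id, nodes in nodes_by_pw.items():
        node_lookup.update({n.node_id: n for n in nodes})
        g = graph_by_id[pw_id]
        sets = cluster_interest_nodes(g, pairs_by_pw[pw_id], m)
        subs = extract_subpathways(g, sets, s=config.s,
                                   interest_node_ids=[n.node_id for n in nodes])
        for sub in subs:
            sub.mean_pcc = mean_region_pcc(sub, node_lookup, profiles,
                                           min_periods=min_periods)
        all_subs.extend(subs)
    return CorspResult(subpathways=all_subs, m=m,
                       pairs_by_pathway=pairs_by_pw,
                       interest_nodes_by_pathway=nodes_by_pw)


def subpathway_table(result: CorspResult) -> pd.DataFrame:
    """Tabular view of extracted regions for TSV export."""
    rows = []
    for sub in result.subpathways:
        rows.append((sub.subpathway_id, sub.pathway_id, len(sub.node_ids),
                     len(sub.interest_node_ids),
                     ";".join(sorted(sub.node_ids)),
                     sub.mean_pcc if sub.mean_pcc is not None else np.nan))
    return pd.DataFrame(rows, columns=["subpathway_id", "pathway_id",
                                       "n_nodes", "n_interest_nodes",
                                       "member_nodes", "mean_region_pcc"])
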