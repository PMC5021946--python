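"""Four reference pathway-identification methods for comparison.

* **Pathway-G** — whole-pathway hypergeometric test on DE genes only.
* **Pathway-M** — whole-pathway hypergeometric test on DE metabolites only.
* **IMPaLA-style joint test** — whole-pathway product of the metabolite and
  gene hypergeometric upper tails (no topology, no subpathways).
* **Subpathway-GM** — subpathway extraction by lenient distance similarity:
  two signature (DE-mapped) nodes merge, together with all nodes on their
  shortest paths, when their hop distance is shorter than n+1; regions of at
  least ``s`` nodes are tested with the combined hypergeometric.

All four share the graph reconstruction, backgrounds and count conventions
of the main method, so observed differences isolate the algorithmic deltas
(use of both molecule types, subpathway resolution, expression correlation).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .corsp_core import (NodeOfInterest, Subpathway, _UnionFind,
                         extract_subpathways, map_interest_to_nodes)
from .enrichment import (Backgrounds, EnrichmentResult, UntestableRegionError,
                         combined_pvalue, region_counts)
from .interest_screen import InterestSet
from .kgml_graph import (PathwayGraph, UNREACHABLE, shortest_path_lengths,
                         shortest_path_nodes)

logger = logging.getLogger(__name__)


@dataclass
class GmConfig:
    """Lenient-distance parameters of the Subpathway-GM baseline."""

    n: int = 1          # merge when shortest path < n + 1
    s: int = 5          # minimum region node count

    def __post_init__(self):
        if self.n < 0:
            raise ValueError("n must be >= 0")
        if self.s < 1:
            raise ValueError("s must be >= 1")


def _whole_pathway_result(graph: PathwayGraph, interest_metabs: set[str],
                          interest_genes: set[str], backgrounds: Backgrounds,
                          gene_to_ko) -> EnrichmentResult | None:
    counts = region_counts(graph, graph.nodes, interest_metabs,
                           interest_genes, backgrounds, gene_to_ko)
    try:
        return combined_pvalue(counts, region_id=graph.pathway_id)
    except UntestableRegionError:
        return None


def pathway_g(de_genes: set[str], graphs: Sequence[PathwayGraph],
              backgrounds: Backgrounds,
              gene_to_ko: Mapping[str, str | Iterable[str]]
              ) -> list[EnrichmentResult]:
    """Whole-pathway gene-only over-representation (metabolite tail neutral).

    A pathway is *potential* — i.e. tested — when at least one DE gene maps
    onto one of its enzyme nodes; pathways with no gene annotation at all are
    skipped with a warning.
    """
    interest = InterestSet(metabolites=set(), genes=set(de_genes))
    out = []
    for g in graphs:
        counts = region_counts(g, g.nodes, set(), set(de_genes),
                               backgrounds, gene_to_ko)
        if counts.t_g == 0:
            logger.warning("%s: no gene annotation; skipped by Pathway-G",
                           g.pathway_id)
            continue
        if not any(n.node_type == "enzyme"
                   for n in map_interest_to_nodes(g, interest, gene_to_ko)):
            continue
        res = combined_pvalue(counts, region_id=g.pathway_id)
        res.p_metab = 1.0
        res.p_combined = res.p_gene
        out.append(res)
    return out


def pathway_m(de_metabs: set[str], graphs: Sequence[PathwayGraph],
              backgrounds: Backgrounds,
              gene_to_ko: Mapping[str, str | Iterable[str]]
              ) -> list[EnrichmentResult]:
    """Whole-pathway metabolite-only over-representation (gene tail neutral)."""
    interest = InterestSet(metabolites=set(de_metabs), genes=set())
    out = []
    for g in graphs:
        counts = region_counts(g, g.nodes, set(de_metabs), set(),
                               backgrounds, gene_to_ko)
        if counts.t_m == 0:
            logger.warning("%s: no compound nodes; skipped by Pathway-M",
                           g.pathway_id)
            continue
        if not any(n.node_type == "compound"
                   for n in map_interest_to_nodes(g, interest, gene_to_ko)):
            continue
        res = combined_pvalue(counts, region_id=g.pathway_id)
        res.p_gene = 1.0
        res.p_combined = res.p_metab
        out.append(res)
    return out


def impala(de_metabs: set[str], de_genes: set[str],
           graphs: Sequence[PathwayGraph], backgrounds: Backgrounds,
           gene_to_ko: Mapping[str, str | Iterable[str]]
           ) -> list[EnrichmentResult]:
    """Whole-pathway joint test: product of the metabolite and gene upper
    tails, no topology.  A pathway is tested when at least one DE molecule of
    either kind maps onto it."""
    interest = InterestSet(metabolites=set(de_metabs), genes=set(de_genes))
    out = []
    for g in graphs:
        if not map_interest_to_nodes(g, interest, gene_to_ko):
            continue
        res = _whole_pathway_result(g, set(de_metabs), set(de_genes),
                                    backgrounds, gene_to_ko)
        if res is not None:
            out.append(res)
    return out


def subpathway_gm(graphs: Sequence[PathwayGraph], de_metabs: set[str],
                  de_genes: set[str], config: GmConfig,
                  backgrounds: Backgrounds,
                  gene_to_ko: Mapping[str, str | Iterable[str]]
                  ) -> tuple[list[Subpathway], list[EnrichmentResult]]:
    """Lenient-distance subpathway extraction on DE-only signature nodes.

    Two signature nodes merge (injecting all nodes on their shortest paths)
    iff their hop distance is strictly shorter than n+1; merged sets of at
    least ``s`` nodes become regions and get the combined hypergeometric.
    """
    signature = InterestSet(metabolites=set(de_metabs), genes=set(de_genes))
    all_subs: list[Subpathway] = []
    results: list[EnrichmentResult] = []
    for g in graphs:
        sig_nodes = map_interest_to_nodes(g, signature, gene_to_ko)
        if not sig_nodes:
            continue
        dist = shortest_path_lengths(g)
        ids = sorted(n.node_id for n in sig_nodes)
        uf = _UnionFind(ids)
        injected: list[tuple[str, set[str]]] = []
        for a, b in itertools.combinations(ids, 2):
            d = dist.distance(a, b)
            if d is not UNREACHABLE and d < config.n + 1:
                uf.union(a, b)
                injected.append((a, shortest_path_nodes(g, a, b)))
        members: dict[str, set[str]] = {}
        for nid in ids:
            members.setdefault(uf.find(nid), set()).add(nid)
        for anchor, path_nodes in injected:
            members[uf.find(anchor)] |= path_nodes
        node_sets = [members[r] for r in sorted(members)]
        subs = extract_subpathways(g, node_sets, s=config.s,
                                   interest_node_ids=ids)
        all_subs.extend(subs)
        for sub in subs:
            counts = region_counts(g, sub.node_ids, set(de_metabs),
                                   set(de_genes), backgrounds, gene_to_ko)
            try:
                results.append(combined_pvalue(counts,
                                               region_id=sub.subpathway_id))
            except UntestableRegionError as exc:
                logger.warning(str(exc))
    return all_subs, results


def comparison_table(per_method: Mapping[str, Sequence[EnrichmentResult]]
                     ) -> pd.DataFrame:
    """Pathway × method p-value matrix.

    Subpathway methods contribute the minimum region p per parent pathway
    (region ids ``path:NNNNN_k`` are folded onto ``path:NNNNN``).  A ``1`` is
    emitted when a method could not test a pathway, matching the published
    reporting convention for "not found".
    """
    def parent(region_id: str) -> str:
        return region_id.rsplit("_", 1)[0] if "_" in region_id.split(":")[-1] \
            else region_id

    per_pathway: dict[str, dict[str, float]] = {}
    for method, results in per_method.items():
        for r in results:
            pw = parent(r.region_id)
            cur = per_pathway.setdefault(pw, {})
            cur[method] = min(cur.get(method, 1.0), r.p_combined)
    rows = []
    for pw in sorted(per_pathway):
        row = {"pathway_id": pw}
        for method in per_method:
            row[method] = per_pathway[pw].get(method, 1.0)
        rows.append(row)
    return pd.DataFrame(rows, columns=["pathway_id", *per_method.keys()])
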