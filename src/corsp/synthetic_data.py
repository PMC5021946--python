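"""Seeded generator of toy pathway collections with planted subpathways.

Emulates the statistical structure the method expects from a matched
metabolomic + transcriptomic two-class study: a collection of KGML pathway
files (random alternating compound–enzyme reaction chains with branches),
one abundance row per compound and one expression row per gene (genes joined
to enzyme nodes through an emitted gene→KO table), and two sample classes.
Background molecules are i.i.d. standard normal per sample; each *planted*
region is a connected set of pathway nodes whose molecules are drawn from a
one-factor equicorrelated Gaussian (within-region correlation ``rho``) with
a class-2 mean shift of ``delta`` standard deviations.  Ground truth (node
ids and molecule ids per planted region) is returned for recovery scoring.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .corsp_core import Subpathway
from .kgml_graph import (Entry, PathwayDefinition, PathwayGraph, Reaction,
                         parse_kgml, reconstruct_graph, serialize_kgml)


@dataclass(frozen=True)
class PlantedRegion:
    pathway_index: int
    size: int          # node count (compounds + enzymes)
    rho: float         # within-region equicorrelation, 0 <= rho < 1
    delta: float       # class-2 mean shift in sd units


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic benchmark.

    Defaults mirror the planted-module benchmark: 20 pathways of 15–40
    nodes, one planted 8-node region with within-region correlation 0.9 and
    a 1.5-sd class shift, 30 samples per class.
    """

    n_pathways: int = 20
    nodes_per_pathway: tuple[int, int] = (15, 40)
    planted: list[PlantedRegion] = field(default_factory=lambda: [
        PlantedRegion(pathway_index=0, size=8, rho=0.9, delta=1.5)])
    n_samples_per_class: int = 30
    missing_rate: float = 0.0

    def __post_init__(self):
        lo, hi = self.nodes_per_pathway
        if not (1 <= lo <= hi):
            raise ValueError("invalid nodes_per_pathway range")
        if self.n_pathways < 1 or self.n_samples_per_class < 2:
            raise ValueError("counts must be positive (>=2 samples/class)")
        for pr in self.planted:
            if not (0 <= pr.pathway_index < self.n_pathways):
                raise ValueError("planted pathway index out of range")
            if pr.size > hi:
                raise ValueError("planted region larger than any pathway")
            if not (0.0 <= pr.rho < 1.0):
                raise ValueError(
                    "rho must lie in [0, 1) for the equicorrelated factor model")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")


@dataclass
class GroundTruth:
    regions: list[dict]  # pathway_id, node_ids, molecules, rho, delta

    def to_json(self) -> str:
        return json.dumps({"regions": self.regions}, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        return cls(regions=json.loads(text)["regions"])


# ---------------------------------------------------------------------------
# Pathway generation
# ---------------------------------------------------------------------------

def _generate_definition(pathway_num: int, n_nodes: int,
                         rng: np.random.Generator) -> PathwayDefinition:
    """Random alternating compound–enzyme reaction chain with branches.

    Grows by reactions (substrate compound → new enzyme → product compound),
    occasionally attaching an extra substrate or an extra new product, which
    yields a connected bipartite graph.  One map entry is always included to
    exercise its removal during reconstruction.
    """
    pid = f"path:{90000 + pathway_num:05d}"
    entries: list[Entry] = []
    reactions: list[Reaction] = []
    c_count = e_count = 0

    def new_compound() -> str:
        nonlocal c_count
        c_count += 1
        eid = f"e{len(entries) + 1}"
        entries.append(Entry(entry_id=eid, kind="compound",
                             kegg_ids=(f"C{pathway_num * 1000 + c_count:05d}",)))
        return eid

    def new_enzyme() -> str:
        nonlocal e_count
        e_count += 1
        eid = f"e{len(entries) + 1}"
        entries.append(Entry(entry_id=eid, kind="enzyme",
                             kegg_ids=(f"K{pathway_num * 1000 + e_count:05d}",)))
        return eid

    compounds = [new_compound()]
    node_count = 1
    while node_count < n_nodes:
        substrate = compounds[int(rng.integers(len(compounds)))]
        enzyme = new_enzyme()
        product = new_compound()
        compounds.append(product)
        substrates = [substrate]
        products = [product]
        node_count += 2
        if len(compounds) > 2 and rng.random() < 0.25:
            extra = compounds[int(rng.integers(len(compounds)))]
            if extra not in substrates and extra not in products:
                substrates.append(extra)
        if node_count < n_nodes and rng.random() < 0.2:
            extra_p = new_compound()
            compounds.append(extra_p)
            products.append(extra_p)
            node_count += 1
        reactions.append(Reaction(substrates=tuple(substrates),
                                  products=tuple(products),
                                  enzymes=(enzyme,)))
    # a map link node, removed at reconstruction
    entries.append(Entry(entry_id=f"e{len(entries) + 1}", kind="map",
                         kegg_ids=(f"map{90000 + pathway_num + 1:05d}",)))
    return PathwayDefinition(pathway_id=pid, title=f"synthetic pathway "
                             f"{pathway_num}", entries=entries,
                             reactions=reactions)


def generate_pathways(config: SimulationConfig, seed: int,
                      out_dir: str | Path | None = None
                      ) -> tuple[dict[str, str], list[PathwayGraph]]:
    """Emit a KGML pathway collection; returns (id → KGML text, graphs).

    Every emitted document round-trips through the KGML parser and graph
    reconstruction; output is byte-identical for a fixed seed.  With
    ``out_dir`` the files are also written as ``<id>.xml``.
    """
    rng = np.random.default_rng(seed)
    lo, hi = config.nodes_per_pathway
    kgml: dict[str, str] = {}
    graphs: list[PathwayGraph] = []
    for p in range(config.n_pathways):
        n_nodes = int(rng.integers(lo, hi + 1))
        defn = _generate_definition(p, n_nodes, rng)
        text = serialize_kgml(defn)
        graph = reconstruct_graph(parse_kgml(text))
        kgml[defn.pathway_id] = text
        graphs.append(graph)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for pid, text in kgml.items():
            (out_dir / f"{pid.replace(':', '_')}.xml").write_text(text)
    return kgml, graphs


# ---------------------------------------------------------------------------
# Expression generation
# ---------------------------------------------------------------------------

def _connected_region(graph: PathwayGraph, size: int,
                      rng: np.random.Generator) -> set[str]:
    """Connected node set grown by BFS from a random start node."""
    if size > len(graph):
        raise ValueError(f"{graph.pathway_id}: planted region size {size} "
                         f"exceeds pathway size {len(graph)}")
    nodes = sorted(graph.nodes)
    start = nodes[int(rng.integers(len(nodes)))]
    region = {start}
    frontier = [start]
    while frontier and len(region) < size:
        current = frontier.pop(0)
        for nb in sorted(graph.graph.neighbors(current)):
            if nb not in region:
                region.add(nb)
                frontier.append(nb)
                if len(region) == size:
                    break
    if len(region) < size:
        raise ValueError(f"{graph.pathway_id}: connected component too small "
                         f"for planted region of size {size}")
    return region


def generate_expression(config: SimulationConfig,
                        graphs: Sequence[PathwayGraph], seed: int
                        ) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series,
                                   dict[str, str], GroundTruth]:
    """Matched metabolite and gene matrices with planted regions.

    Returns (metabolite matrix, gene matrix, group labels, gene→KO mapping,
    ground truth).  One gene per KO id (gene id ``g`` + the KO digits);
    samples ``S001..`` labelled ``A`` then ``B``.
    """
    rng = np.random.default_rng(seed)
    compounds: list[str] = []
    kos: list[str] = []
    for g in graphs:
        for nid in sorted(g.compound_nodes()):
            compounds.extend(g.kegg_ids(nid))
        for nid in sorted(g.enzyme_nodes()):
            kos.extend(g.kegg_ids(nid))
    compounds = sorted(set(compounds))
    kos = sorted(set(kos))
    gene_to_ko = {f"g{k[1:]}": k for k in kos}
    genes = sorted(gene_to_ko)
    ko_to_gene = {v: k for k, v in gene_to_ko.items()}

    n_per = config.n_samples_per_class
    samples = [f"S{i + 1:03d}" for i in range(2 * n_per)]
    labels = pd.Series(["A"] * n_per + ["B"] * n_per, index=samples,
                       name="group")

    molecules = compounds + genes
    data = pd.DataFrame(rng.standard_normal((len(molecules), 2 * n_per)),
                        index=molecules, columns=samples)

    truth_regions = []
    for pr in config.planted:
        graph = graphs[pr.pathway_index]
        region_nodes = _connected_region(graph, pr.size, rng)
        mols: list[str] = []
        for nid in sorted(region_nodes):
            if graph.node_type(nid) == "compound":
                mols.extend(graph.kegg_ids(nid))
            else:
                mols.extend(ko_to_gene[k] for k in graph.kegg_ids(nid)
                            if k in ko_to_gene)
        mols = sorted(set(mols))
        # one-factor equicorrelation: x = sqrt(rho) z + sqrt(1-rho) eps
        z = rng.standard_normal(2 * n_per)
        eps = rng.standard_normal((len(mols), 2 * n_per))
        x = np.sqrt(pr.rho) * z + np.sqrt(1.0 - pr.rho) * eps
        x[:, n_per:] += pr.delta
        data.loc[mols] = x
        truth_regions.append({"pathway_id": graph.pathway_id,
                              "node_ids": sorted(region_nodes),
                              "molecules": mols,
                              "rho": pr.rho, "delta": pr.delta})

    metab = data.loc[compounds].copy()
    gene = data.loc[genes].copy()
    if config.missing_rate > 0:
        mask = rng.random(metab.shape) < config.missing_rate
        metab = metab.mask(mask)
    return metab, gene, labels, gene_to_ko, GroundTruth(regions=truth_regions)


# ---------------------------------------------------------------------------
# Recovery scoring
# ---------------------------------------------------------------------------

@dataclass
class RecoveryRecord:
    pathway_id: str
    best_region_id: str | None
    jaccard: float
    detected: bool


def node_jaccard(a: set[str] | frozenset[str], b: set[str] | frozenset[str]
                 ) -> float:
    if not a and not b:
        return 1.0
    union = len(set(a) | set(b))
    return len(set(a) & set(b)) / union if union else 0.0


def evaluate_recovery(found: Sequence[Subpathway], truth: GroundTruth,
                      jaccard_threshold: float = 0.8,
                      significant_ids: set[str] | None = None
                      ) -> list[RecoveryRecord]:
    """Best node-level Jaccard match per planted region.

    A region counts as *detected* when its best match reaches the Jaccard
    threshold and (when ``significant_ids`` is given) that match is among
    the significant regions.
    """
    out = []
    for region in truth.regions:
        t_nodes = set(region["node_ids"])
        best_j, best_id = 0.0, None
        for sub in found:
            if sub.pathway_id != region["pathway_id"]:
                continue
            j = node_jaccard(t_nodes, sub.node_ids)
            if j > best_j:
                best_j, best_id = j, sub.subpathway_id
        detected = best_j >= jaccard_threshold and (
            significant_ids is None or best_id in significant_ids)
        out.append(RecoveryRecord(pathway_id=region["pathway_id"],
                                  best_region_id=best_id, jaccard=best_j,
                                  detected=detected))
    return out
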