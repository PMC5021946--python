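"""Combined metabolite/gene hypergeometric enrichment of subpathway regions.

A region is tested separately against the metabolite background and the gene
background.  With m_m background metabolites, n_m interest metabolites, t_m
metabolites annotated to the region and r_m of them of interest, the
metabolite component is the hypergeometric upper tail P[X >= r_m] for X ~
Hypergeom(m_m, t_m, n_m); the gene component is defined analogously from
(m_g, t_g, n_g, r_g).  The default combined p-value is the product of the two
tails (a component with no annotated molecules contributes the neutral value
1); Fisher's method is available as an alternative composition rule.
Regions are called significant on the raw combined p-value; a
Benjamini–Hochberg adjusted column is reported alongside for reference only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .corsp_core import NodeOfInterest, Subpathway
from .kgml_graph import PathwayGraph

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Backgrounds:
    """Reference molecule universes (e.g. HMDB metabolome, KEGG genome)."""

    metabolites: frozenset[str]
    genes: frozenset[str]

    @classmethod
    def from_lists(cls, metabolites: Iterable[str], genes: Iterable[str]):
        return cls(metabolites=frozenset(metabolites), genes=frozenset(genes))


@dataclass(frozen=True)
class EnrichmentCounts:
    m_m: int  # background metabolites
    m_g: int  # background genes
    n_m: int  # interest metabolites
    n_g: int  # interest genes
    t_m: int  # background metabolites annotated to the region
    t_g: int  # background genes annotated to the region
    r_m: int  # interest metabolites in the region
    r_g: int  # interest genes in the region

    def validate(self) -> None:
        if not (0 <= self.t_m <= self.m_m and 0 <= self.t_g <= self.m_g):
            raise ValueError("region counts exceed background counts")
        if not (0 <= self.n_m <= self.m_m and 0 <= self.n_g <= self.m_g):
            raise ValueError("interest counts exceed background counts")
        if self.r_m > min(self.n_m, self.t_m) or self.r_g > min(self.n_g, self.t_g):
            raise ValueError("observed overlap exceeds min(interest, region)")
        if min(self.r_m, self.r_g) < 0:
            raise ValueError("negative counts")


@dataclass
class EnrichmentResult:
    region_id: str
    counts: EnrichmentCounts
    p_metab: float
    p_gene: float
    p_combined: float
    significant: bool = False


def hypergeom_upper_tail(population: int, category: int, draws: int,
                         observed: int) -> float:
    """Exact hypergeometric upper tail P[X >= observed].

    X counts category members among ``draws`` draws without replacement from
    a ``population`` containing ``category`` members.  observed = 0 gives 1;
    an observed beyond min(draws, category) gives 0 by convention.
    """
    if population < 0 or not (0 <= category <= population) \
            or not (0 <= draws <= population):
        raise ValueError(
            f"inconsistent counts: population={population}, "
            f"category={category}, draws={draws}")
    if observed <= 0:
        return 1.0
    if observed > min(draws, category):
        return 0.0
    return float(stats.hypergeom.sf(observed - 1, population, category, draws))


class UntestableRegionError(ValueError):
    """Region with no annotated metabolites and no annotated genes."""


def combined_pvalue(counts: EnrichmentCounts, region_id: str = "",
                    method: str = "product") -> EnrichmentResult:
    """Component and combined p-values for one region.

    ``method`` is ``"product"`` (default: p_metab * p_gene) or ``"fisher"``
    (Fisher's chi-square combination).  A component with zero annotated
    molecules (t = 0) contributes the neutral value 1; a region with neither
    metabolites nor genes annotated is untestable.
    """
    counts.validate()
    if counts.t_m == 0 and counts.t_g == 0:
        raise UntestableRegionError(
            f"region {region_id or '<anon>'} annotates no background "
            "metabolites and no background genes")
    p_metab = 1.0 if counts.t_m == 0 else hypergeom_upper_tail(
        counts.m_m, counts.t_m, counts.n_m, counts.r_m)
    p_gene = 1.0 if counts.t_g == 0 else hypergeom_upper_tail(
        counts.m_g, counts.t_g, counts.n_g, counts.r_g)
    if method == "product":
        p_comb = p_metab * p_gene
    elif method == "fisher":
        p_comb = float(stats.combine_pvalues([p_metab, p_gene],
                                             method="fisher").pvalue)
    else:
        raise ValueError(f"unknown combination method {method!r}")
    return EnrichmentResult(region_id=region_id, counts=counts,
                            p_metab=p_metab, p_gene=p_gene,
                            p_combined=p_comb)


# ---------------------------------------------------------------------------
# Counting molecules in regions
# ---------------------------------------------------------------------------

def _ko_index(gene_to_ko: Mapping[str, str | Iterable[str]]
              ) -> dict[str, set[str]]:
    idx: dict[str, set[str]] = {}
    for g, kos in gene_to_ko.items():
        if isinstance(kos, str):
            kos = [kos]
        for ko in kos:
            idx.setdefault(ko, set()).add(g)
    return idx


def region_counts(graph: PathwayGraph, node_ids: Iterable[str],
                  interest_metabolites: set[str], interest_genes: set[str],
                  backgrounds: Backgrounds,
                  gene_to_ko: Mapping[str, str | Iterable[str]]
                  ) -> EnrichmentCounts:
    """Eight-count table for an arbitrary node set of one pathway.

    Region metabolites are the compound ids of compound nodes intersected
    with the metabolite background; region genes are all genes annotated (via
    gene→KO) to the region's enzyme KO ids, intersected with the gene
    background.  Interest molecules outside the background are ignored so the
    hypergeometric urn stays consistent.
    """
    ko_idx = _ko_index(gene_to_ko)
    region_metabs: set[str] = set()
    region_genes: set[str] = set()
    for nid in node_ids:
        ids = graph.kegg_ids(nid)
        if graph.node_type(nid) == "compound":
            region_metabs.update(ids)
        else:
            for ko in ids:
                region_genes.update(ko_idx.get(ko, ()))
    region_metabs &= backgrounds.metabolites
    region_genes &= backgrounds.genes
    int_m = interest_metabolites & backgrounds.metabolites
    int_g = interest_genes & backgrounds.genes
    return EnrichmentCounts(
        m_m=len(backgrounds.metabolites), m_g=len(backgrounds.genes),
        n_m=len(int_m), n_g=len(int_g),
        t_m=len(region_metabs), t_g=len(region_genes),
        r_m=len(region_metabs & int_m), r_g=len(region_genes & int_g))


def enrich_subpathways(subpathways: Sequence[Subpathway],
                       graphs: Sequence[PathwayGraph],
                       interest_metabolites: set[str],
                       interest_genes: set[str],
                       backgrounds: Backgrounds,
                       gene_to_ko: Mapping[str, str | Iterable[str]],
                       method: str = "product") -> list[EnrichmentResult]:
    """Combined enrichment for every region; untestable regions are skipped
    with a warning."""
    graph_by_id = {g.pathway_id: g for g in graphs}
    out = []
    for sub in subpathways:
        g = graph_by_id[sub.pathway_id]
        counts = region_counts(g, sub.node_ids, interest_metabolites,
                               interest_genes, backgrounds, gene_to_ko)
        try:
            out.append(combined_pvalue(counts, region_id=sub.subpathway_id,
                                       method=method))
        except UntestableRegionError as exc:
            logger.warning(str(exc))
    return out


def significance_filter(results: Sequence[EnrichmentResult],
                        alpha: float = 0.05) -> list[EnrichmentResult]:
    """Regions with combined p < alpha, sorted ascending by p."""
    sig = [r for r in results if r.p_combined < alpha]
    for r in sig:
        r.significant = True
    return sorted(sig, key=lambda r: (r.p_combined, r.region_id))


def enrichment_table(results: Sequence[EnrichmentResult],
                     alpha: float = 0.05) -> pd.DataFrame:
    """TSV-ready table with a BH-adjusted column (reference only; the
    significance call uses the raw combined p)."""
    if not results:
        return pd.DataFrame(columns=["region_id", "t_m", "r_m", "t_g", "r_g",
                                     "p_metab", "p_gene", "p_combined",
                                     "p_bh", "significant"])
    p = np.array([r.p_combined for r in results])
    p_bh = multipletests(p, method="fdr_bh")[1]
    rows = []
    for r, adj in zip(results, p_bh):
        rows.append((r.region_id, r.counts.t_m, r.counts.r_m, r.counts.t_g,
                     r.counts.r_g, r.p_metab, r.p_gene, r.p_combined,
                     float(adj), bool(r.p_combined < alpha)))
    df = pd.DataFrame(rows, columns=["region_id", "t_m", "r_m", "t_g", "r_g",
                                     "p_metab", "p_gene", "p_combined",
                                     "p_bh", "significant"])
    return df.sort_values(["p_combined", "region_id"]).reset_index(drop=True)
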