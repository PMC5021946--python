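"""In-memory end-to-end analysis: screen → map → score → cluster → enrich.

Shared by the command-line front end and the resampling stability harness so
both run byte-identical logic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .corsp_core import (CorspResult, SubpathwayConfig, identify_subpathways)
from .enrichment import (Backgrounds, EnrichmentResult, enrich_subpathways,
                         significance_filter)
from .interest_screen import (InterestSet, build_interest_set,
                              correlation_screen, de_screen_wilcoxon,
                              sam_screen)
from .kgml_graph import PathwayGraph


@dataclass
class PipelineConfig:
    """Thresholds and knobs of one full analysis run.

    Defaults follow common practice for this analysis: metabolite DE at
    Wilcoxon p < 0.05, gene DE at SAM FDR < 0.001, correlation screen at
    signed Pcc > 0.8, region significance at raw combined p < 0.05.
    ``sam_seed`` fixes the SAM permutation stream so the screen (and hence
    the whole run) is reproducible.
    """

    metab_p: float = 0.05
    gene_fdr: float = 0.001
    pcc_cutoff: float = 0.8
    use_abs_corr: bool = False
    alpha: float = 0.05
    subpathway: SubpathwayConfig = field(default_factory=SubpathwayConfig)
    combine_method: str = "product"
    sam_n_perm: int = 100
    sam_seed: int = 0
    min_periods: int = 5


@dataclass
class AnalysisResult:
    interest: InterestSet
    corsp: CorspResult
    enrichment: list[EnrichmentResult]
    significant: list[EnrichmentResult]
    screen_stats: dict = field(default_factory=dict)

    @property
    def significant_ids(self) -> set[str]:
        return {r.region_id for r in self.significant}

    def subpathway_by_id(self, region_id: str):
        for sub in self.corsp.subpathways:
            if sub.subpathway_id == region_id:
                return sub
        raise KeyError(region_id)


def screen_interest(metab: pd.DataFrame, gene: pd.DataFrame,
                    labels: pd.Series, config: PipelineConfig
                    ) -> tuple[InterestSet, dict[str, tuple[float, float]]]:
    """DE + correlation screening, unioned into the interest set.

    Also returns per-molecule (statistic, p-or-FDR) pairs for reporting:
    Wilcoxon p for metabolites, the SAM d-statistic and selection FDR for
    genes.
    """
    de_metab, wilcoxon_p = de_screen_wilcoxon(metab, labels,
                                              p_cutoff=config.metab_p)
    sam = sam_screen(gene, labels, fdr_cutoff=config.gene_fdr,
                     n_perm=config.sam_n_perm, seed=config.sam_seed)
    corr_metab, corr_gene = correlation_screen(
        metab, gene, cutoff=config.pcc_cutoff, use_abs=config.use_abs_corr,
        min_periods=config.min_periods)
    stats = {m: (float("nan"), float(p)) for m, p in wilcoxon_p.items()}
    fdr = sam.fdr_at_delta if sam.fdr_at_delta is not None else float("nan")
    stats.update({g: (float(sam.d[g]), fdr if g in sam.selected
                      else float("nan")) for g in gene.index})
    interest = build_interest_set(de_metab, sam.selected, corr_metab,
                                  corr_gene)
    return interest, stats


def run_analysis(metab: pd.DataFrame, gene: pd.DataFrame, labels: pd.Series,
                 graphs: Sequence[PathwayGraph],
                 gene_to_ko: Mapping[str, str | Iterable[str]],
                 backgrounds: Backgrounds,
                 config: PipelineConfig | None = None,
                 interest: InterestSet | None = None) -> AnalysisResult:
    """One full run; pass ``interest`` to skip re-screening (frozen mode)."""
    config = config or PipelineConfig()
    labels = labels.loc[[s for s in labels.index if s in metab.columns
                         and s in gene.columns]]
    screen_stats: dict = {}
    if interest is None:
        interest, screen_stats = screen_interest(
            metab[labels.index], gene[labels.index], labels, config)
    profiles = pd.concat([metab, gene])
    corsp = identify_subpathways(graphs, interest, profiles, gene_to_ko,
                                 config=config.subpathway,
                                 min_periods=config.min_periods)
    enr = enrich_subpathways(corsp.subpathways, graphs,
                             interest.metabolites, interest.genes,
                             backgrounds, gene_to_ko,
                             method=config.combine_method)
    sig = significance_filter(enr, alpha=config.alpha)
    return AnalysisResult(interest=interest, corsp=corsp, enrichment=enr,
                          significant=sig, screen_stats=screen_stats)
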