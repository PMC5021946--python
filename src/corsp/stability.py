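"""Resampling stability of the identified subpathways.

The reference analysis on the full data fixes the original significant
regions.  Each replicate then draws, per class and without replacement, a
``fraction`` of the samples (floor rule, e.g. 16 → 12 and 24 → 18 at 75%)
simultaneously from both matrices, re-runs the full pipeline, and counts how
many original significant regions are *recalled*.  Region identity across
reruns is matched by parent pathway plus member-node Jaccard (default 0.5),
since regrown regions shift slightly.  One master seed spawns the
per-replicate sample draws; the screening seed stays fixed so fraction = 1
reproduces the reference run exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .enrichment import Backgrounds
from .kgml_graph import PathwayGraph
from .pipeline import AnalysisResult, PipelineConfig, run_analysis
from .synthetic_data import node_jaccard


@dataclass
class ReplicateRecord:
    replicate: int
    seed: int
    sample_ids: tuple[str, ...]
    recalled_ids: tuple[str, ...]
    n_original: int

    @property
    def recall(self) -> float:
        return len(self.recalled_ids) / self.n_original if self.n_original \
            else float("nan")


@dataclass
class StabilityReport:
    n_replicates: int
    seed: int
    fraction: float
    original_ids: tuple[str, ...]
    replicates: list[ReplicateRecord]

    @property
    def mean_recall(self) -> float:
        return float(np.mean([r.recall for r in self.replicates]))

    def to_frame(self) -> pd.DataFrame:
        rows = [(r.replicate, len(r.recalled_ids), r.n_original, r.recall)
                for r in self.replicates]
        return pd.DataFrame(rows, columns=["replicate", "n_recalled",
                                           "n_original", "recall"])


def _stratified_draw(labels: pd.Series, fraction: float,
                     rng: np.random.Generator) -> list[str]:
    chosen: list[str] = []
    for cls in sorted(pd.unique(labels)):
        members = sorted(labels.index[labels == cls])
        k = int(np.floor(fraction * len(members)))
        idx = rng.choice(len(members), size=k, replace=False)
        chosen.extend(members[i] for i in sorted(idx))
    return chosen


def _recalled(original: AnalysisResult, replicate: AnalysisResult,
              jaccard_threshold: float) -> list[str]:
    rep_sig = [replicate.subpathway_by_id(rid)
               for rid in replicate.significant_ids]
    out = []
    for rid in sorted(original.significant_ids):
        sub = original.subpathway_by_id(rid)
        for rep_sub in rep_sig:
            if rep_sub.pathway_id == sub.pathway_id and \
                    node_jaccard(sub.node_ids, rep_sub.node_ids) >= \
                    jaccard_threshold:
                out.append(rid)
                break
    return out


def run_stability(metab: pd.DataFrame, gene: pd.DataFrame, labels: pd.Series,
                  graphs: Sequence[PathwayGraph],
                  gene_to_ko: Mapping[str, str | Iterable[str]],
                  backgrounds: Backgrounds,
                  pipeline_config: PipelineConfig | None = None,
                  fraction: float = 0.75, n_replicates: int = 80,
                  seed: int = 0, refresh_interest: bool = True,
                  jaccard_threshold: float = 0.5,
                  reference: AnalysisResult | None = None) -> StabilityReport:
    """Stratified-subsample stability analysis.

    ``refresh_interest`` re-screens molecules of interest per replicate
    (default); otherwise the reference interest set is frozen and only the
    downstream steps are re-run.  Deterministic for a fixed ``seed``.
    """
    pipeline_config = pipeline_config or PipelineConfig()
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    for cls in pd.unique(labels):
        if int(np.floor(fraction * (labels == cls).sum())) < 2:
            raise ValueError(
                f"fraction {fraction} leaves fewer than 2 samples in class "
                f"{cls!r}")
    if reference is None:
        reference = run_analysis(metab, gene, labels, graphs, gene_to_ko,
                                 backgrounds, pipeline_config)
    master = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                   for s in master.spawn(n_replicates)]
    replicates: list[ReplicateRecord] = []
    n_orig = len(reference.significant_ids)
    for i, rep_seed in enumerate(child_seeds):
        rng = np.random.default_rng(rep_seed)
        sample_ids = _stratified_draw(labels, fraction, rng)
        sub_labels = labels.loc[sample_ids]
        rep = run_analysis(metab[sample_ids], gene[sample_ids], sub_labels,
                           graphs, gene_to_ko, backgrounds, pipeline_config,
                           interest=None if refresh_interest
                           else reference.interest)
        recalled = _recalled(reference, rep, jaccard_threshold)
        replicates.append(ReplicateRecord(
            replicate=i, seed=rep_seed, sample_ids=tuple(sample_ids),
            recalled_ids=tuple(recalled), n_original=n_orig))
    return StabilityReport(n_replicates=n_replicates, seed=seed,
                           fraction=fraction,
                           original_ids=tuple(sorted(reference.significant_ids)),
                           replicates=replicates)
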