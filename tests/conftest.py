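import numpy as np
import pytest

from corsp.enrichment import Backgrounds
from corsp.kgml_graph import (Entry, PathwayDefinition, Reaction,
                              reconstruct_graph)
from corsp.synthetic_data import (PlantedRegion, SimulationConfig,
                                  generate_expression, generate_pathways)


def make_definition(pathway_id="path:00001", entries=(), reactions=()):
    return PathwayDefinition(pathway_id=pathway_id, title="fixture",
                             entries=list(entries), reactions=list(reactions))


def chain_definition(n_compounds, pathway_id="path:00001"):
    """Linear pathway C1 - E1 - C2 - E2 - ... with n_compounds compounds."""
    entries, reactions = [], []
    for i in range(1, n_compounds + 1):
        entries.append(Entry(f"c{i}", "compound", (f"C{i:05d}",)))
    for i in range(1, n_compounds):
        entries.append(Entry(f"k{i}", "enzyme", (f"K{i:05d}",)))
        reactions.append(Reaction(substrates=(f"c{i}",),
                                  products=(f"c{i + 1}",),
                                  enzymes=(f"k{i}",)))
    return make_definition(pathway_id, entries, reactions)


def random_graph(rng, max_nodes=30):
    """Random bipartite pathway graph via random reactions."""
    n_compounds = int(rng.integers(2, max(3, max_nodes // 2)))
    n_enzymes = int(rng.integers(1, max(2, max_nodes - n_compounds)))
    entries = [Entry(f"c{i}", "compound", (f"C{i:05d}",))
               for i in range(n_compounds)]
    entries += [Entry(f"k{i}", "enzyme", (f"K{i:05d}",))
                for i in range(n_enzymes)]
    reactions = []
    for i in range(n_enzymes):
        subs = rng.choice(n_compounds, size=int(rng.integers(1, 3)),
                          replace=False)
        prods = rng.choice(n_compounds, size=int(rng.integers(1, 3)),
                           replace=False)
        reactions.append(Reaction(
            substrates=tuple(f"c{j}" for j in subs),
            products=tuple(f"c{j}" for j in prods),
            enzymes=(f"k{i}",)))
    return reconstruct_graph(make_definition("path:00099", entries, reactions))


@pytest.fixture(scope="session")
def planted_dataset():
    """Default synthetic study: 20 pathways, one planted 8-node region
    (rho=0.9, delta=1.5 sd), 30 samples per class."""
    cfg = SimulationConfig()
    _, graphs = generate_pathways(cfg, seed=11)
    metab, gene, labels, gene_to_ko, truth = generate_expression(
        cfg, graphs, seed=12)
    backgrounds = Backgrounds.from_lists(metab.index, gene.index)
    return dict(config=cfg, graphs=graphs, metab=metab, gene=gene,
                labels=labels, gene_to_ko=gene_to_ko, truth=truth,
                backgrounds=backgrounds)


@pytest.fixture(scope="session")
def small_planted_dataset():
    """Smaller planted study for fast stability / baseline tests."""
    cfg = SimulationConfig(n_pathways=6, nodes_per_pathway=(12, 20),
                           planted=[PlantedRegion(0, 6, 0.9, 1.5)],
                           n_samples_per_class=20)
    _, graphs = generate_pathways(cfg, seed=21)
    metab, gene, labels, gene_to_ko, truth = generate_expression(
        cfg, graphs, seed=22)
    backgrounds = Backgrounds.from_lists(metab.index, gene.index)
    return dict(config=cfg, graphs=graphs, metab=metab, gene=gene,
                labels=labels, gene_to_ko=gene_to_ko, truth=truth,
                backgrounds=backgrounds)
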