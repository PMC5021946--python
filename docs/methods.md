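# Methods

This note records the model underlying `corsp`, the conventions chosen where
the procedure leaves room, and what the synthetic benchmark does and does not
demonstrate.

## Pathway graphs

Pathways are undirected bipartite compound–enzyme graphs reconstructed from
KGML. Edges come only from reactions: each substrate compound is joined to
each catalysing enzyme node, each enzyme node to each product compound.
Conventions:

- Map-link entries are removed; entries of unknown type are kept in the
  parse product (kind `other`) but never become graph nodes.
- Entries sharing an identical KEGG id set collapse to one node, so
  distances reflect chemistry rather than drawing layout. An entry listing
  several KO ids stays one enzyme node carrying all of them.
- Reactions with no resolvable enzyme are skipped with a warning — no
  compound–compound shortcut is ever invented.
- KGML `relation` elements (ECrel/PPrel) are ignored; edges are
  reaction-derived only.
- Directionality and stoichiometry are deliberately not modelled.

Distances are unweighted BFS hop counts; unreachable pairs carry a `None`
sentinel and never participate in clustering. When several shortest paths
tie, *all* of their nodes are considered "on the shortest path" (a node v
qualifies iff d(i,v) + d(v,j) = d(i,j)). This is deterministic and needs no
tie-breaking; it can only add nodes relative to picking one arbitrary path.

## Screening

- **Metabolites:** two-sided Wilcoxon rank-sum per molecule, default
  p < 0.05 (raw, no multiplicity correction — matching the convention of
  the analysis this package implements). The exact null is enumerated for
  pooled n ≤ 12 without ties; otherwise the normal approximation with tie
  and continuity corrections is used. Completely tied data give p = 1 with
  a warning.
- **Genes:** SAM-type moderated statistic d = (mean difference)/(s + s₀)
  with the fudge factor s₀ chosen by the percentile-minimisation rule
  (minimise the coefficient of variation of the within-window spread of d
  across windows of the per-gene standard error s; candidates are the 5 %
  quantiles of s). The FDR at a candidate |d| threshold is the median
  permutation exceedance count over the observed exceedance count
  (default 100 label permutations, seeded); the smallest threshold with
  estimated FDR ≤ 0.001 is selected. Zero-variance genes get d = 0 and are
  flagged.
- **Correlation screen:** Pearson on pairwise-complete observations with a
  floor of 5 shared samples per pair; pairs below the floor, and molecules
  with zero variance on the complete pairs, are undefined (NaN) and never
  qualify. A molecule is of interest when any
  metabolite–metabolite, metabolite–gene or gene–gene pair exceeds the
  cutoff (default signed c > 0.8; an absolute-value switch exists for users
  who consider anti-correlation informative). A row-blocked scan gives
  identical results with bounded memory.

The interest set is the union of DE and high-correlation molecules, with
per-molecule provenance flags.

## CorSP scoring and region growth

The pair score defaults to β·c/d with β = 10. The defining requirements are
strict monotonicity — increasing in c, decreasing in d — and any
user-supplied form must satisfy them; the linear-in-c, reciprocal-in-d
default is the simplest such form and reduces to pure-topology clustering
when correlations are constant. Under the signed default, strongly negative
pairs never pass a positive threshold; the absolute-correlation switch
changes that.

Nodes mapping several molecules aggregate their cross-pair correlations by
the signed value of maximum magnitude (default) or the arithmetic mean.

The threshold m is chosen **globally**: all finite pair scores from the
whole pathway collection are pooled, and m is the largest *observed* score
value with at least 70 % of scores strictly above it. Restricting candidates
to observed values makes the "largest such value" well defined (the passing
fraction is a right-continuous step function with no attainable supremum
over the reals); if even the minimum fails — e.g. all scores equal — the
largest representable value below the minimum is returned, so everything
passes. Pairs merge when score > m (strict), consistent with the candidate
rule.

Clustering is a disjoint-set fixpoint: each passing pair unions its two
interest nodes and injects every node on any of their shortest paths into
the merged set. The result is independent of pair processing order, and
raising m never enlarges a set. Merged sets of ≥ s = 5 nodes become regions;
each region's induced subgraph is connected by construction (each pair
contributes a path containing both endpoints, and components only merge
through shared interest nodes) and this is asserted. Region ids are
`<pathway>_<k>` with k by descending node count, ties broken by the
lexicographically smallest member node id — the numbering convention is
ours, chosen for determinism.

With all correlations equal to 1 and m = β/(n+1), the clustering is exactly
the lenient-distance rule (merge iff d < n+1) of the Subpathway-GM
reference method; the test suite verifies this node-for-node against an
independently implemented lenient-distance route.

## Significance

Each region is tested against configurable background universes (intended to
stand for, e.g., the HMDB metabolome and the KEGG genome; defaulting to the
profiled molecules when no lists are supplied). The metabolite component is
the exact hypergeometric upper tail P[X ≥ r_m] with population m_m, category
t_m, draws n_m; the gene component analogously. Interest molecules outside
the background are dropped from the counts so the urn stays consistent.

The combined p-value is the **product** of the two tails, with Fisher's
method available as an option. The product of two valid tails is not itself
a uniformly distributed p-value — it is conservative for independent
components — and the two composition rules can rank regions differently;
this is surfaced to users rather than silently assumed. A component with no
annotated molecules contributes the neutral value 1; a region annotating
neither metabolites nor genes is untestable and skipped with a warning.
Regions are called significant on the raw combined p < α = 0.05;
Benjamini–Hochberg adjusted values are reported as an additional column
only.

Baselines share all counting conventions so that differences between
methods isolate the algorithmic deltas. A pathway is "potential" for a
method when at least one of that method's interest molecules maps onto it;
pathways a method cannot test are reported with p = 1 in the comparison
table. The Subpathway-GM lenient-distance parameter defaults to n = 1
(a choice of this package; it is configurable).

## Stability analysis

The reference run fixes the original significant regions. Each replicate
draws ⌊fraction·n⌋ samples per class (e.g. 16 → 12 and 24 → 18 at 75 %)
without replacement, simultaneously from both matrices, and re-runs the
full pipeline — by default including re-screening of the interest molecules;
a frozen-interest mode re-uses the reference interest set. Regions are
matched across reruns by parent pathway plus member-node Jaccard ≥ 0.5
(configurable), since regrown regions shift slightly. One master seed
spawns per-replicate draw seeds; the SAM permutation seed is part of the
pipeline configuration and therefore identical across replicates, which
makes the fraction = 1 limit reproduce the reference run exactly (every
replicate recalls 100 %).

## Synthetic benchmark

The generator emulates the statistical skeleton of a matched two-class
metabolome/transcriptome study: random alternating compound–enzyme reaction
chains with branches (connected, bipartite, serialized as valid KGML, one
map entry included to exercise its removal), one abundance row per compound
and one expression row per gene (one gene per KO), i.i.d. standard-normal
background molecules, and planted connected regions whose molecules follow
a one-factor equicorrelated Gaussian (within-region correlation ρ) with a
class-2 mean shift δ in sd units. The factor construction restricts ρ to
[0, 1). Metabolite missingness is injectable at a configurable rate to
exercise pairwise-complete correlations.

Default study conditions: 20 pathways of 15–40 nodes, one planted 8-node
region with ρ = 0.9 and δ = 1.5, 30 samples per class. These sizes keep a
full analysis under a second while giving the screens high power on planted
molecules; the stability and recovery experiments in the tests and the
acceptance script use 10–20 seeded repetitions of such studies.

What the generator does **not** emulate: mass-spectrometry intensity
distributions, heavy tails, batch effects, the many-to-one name-mapping of
real metabolomics identifiers, or realistic KEGG topology (real maps are
denser and bushier than the generated chains). Passing benchmarks here
demonstrates correctness of the machinery on data satisfying the method's
own assumptions, not performance on real cohorts.

## Observed behaviour and limitations

Two structural properties of the procedure are worth knowing, and the test
suite documents both quantitatively:

- **The 70 % rule adapts m to whatever is pooled.** By construction about
  70 % of interest-node pairs merge regardless of how much genuine signal
  exists. When the interest set contains false positives (the raw p < 0.05
  metabolite screen admits ~5 % of null molecules by design), a single
  false interest node in a pathway can merge into a genuine region through
  a weak pair whose score clears the (low) threshold, injecting its whole
  shortest path. On the synthetic benchmark this dilutes the node-level
  Jaccard of the recovered planted region below 0.8 in roughly one run in
  five, even though the region almost always contains every true node.
- **Enrichment after selection is anticonservative.** Regions are grown
  around interest nodes and then tested for enrichment of interest
  molecules; under a global null this circularity yields significant
  regions in ~10 % of pathways at α = 0.05 rather than 5 %. This is a
  property of the subpathway strategy itself (the lenient-distance
  reference method shares it), not of the implementation; users comparing
  methods should rely on the shared-background comparison table and treat
  absolute subpathway p-values with caution.

Other limitations: no cross-pathway redundancy reduction (overlapping maps
are tested independently); no directed or stoichiometric modelling; the
combined-test composition rule (product vs Fisher) is a convention the user
should fix per study.
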