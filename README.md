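# bowtiemap

Topological decomposition and analysis of directed molecular interaction
maps — the kind curated in CellDesigner for a complex disease, where
chemical species (proteins, genes, RNAs, small molecules) alternate with
explicit reaction nodes (`re1`, `re2`, …) and an interaction between two
species always runs through a reaction node.

It is aimed at systems biologists who have an interaction map (SIF or an
SBML/CellDesigner subset) plus node attributes (tissue tags, compartments,
entity classes) and want to answer: where is the cyclic regulatory core of
the map, which feedback cycles does it contain, how does the map split into
modules around those cycles, which nodes are hubs, how do tissue-specific
sub-maps overlap, and which annotation terms are over-represented in a
module.

## What it computes

1. **Bow-tie decomposition** — the centre (union of non-trivial strongly
   connected components), the IN layer (reaches the centre), the OUT layer
   (reached from it) and OTHER.
2. **Relevant cycles** — cycles of the centre that are not GF(2) sums of
   strictly shorter cycles, i.e. members of some minimum cycle basis; these
   are candidate feedback structures.
3. **Module assembly** — cycles sharing more than half their nodes merge
   into module cores; periphery components attach to the core they touch
   (majority of linking nodes, ties to the largest core); leftovers form a
   residual module.
4. **Topology reports** — N, E, weak components, mean distinct neighbours,
   shortest-path mean/variance/diameter over reachable ordered pairs,
   density 2E/(N(N−1)), log-log OLS power-law fits of the in/out degree
   distributions (zero-degree nodes excluded; frequency(k) ∝ k^−γ), and
   hubs (species with degree strictly above a threshold).
5. **Tissue sub-maps** — induced per-tag graphs, the cross-tissue node
   overlap matrix, and classification of shared species by whether their
   species-level neighbourhoods agree across tissues.
6. **Enrichment** — one-sided hypergeometric over-representation of
   annotation terms with Bonferroni and Benjamini–Hochberg control at 0.01.
7. **Synthetic maps** — a seeded generator with planted cycles, modules,
   hubs, tissue tags and an enriched term, so the whole chain is testable
   with known ground truth.

## Worked example

```sh
bowtiemap simulate  --out results/simulated --seed 1
bowtiemap decompose --network results/simulated/network.sif \
                    --attrs results/simulated/attributes.tsv \
                    --out results/decomposition
```

or equivalently `python analysis/01_simulate.py && python
analysis/02_decompose.py`, which prints:

```
bow tie: center=30 in=422 out=86 other=309
relevant cycles: 2; modules (incl. residual): 3
  module 1: 360 nodes (core 16)
  module 2: 470 nodes (core 14)
  module 3: 17 nodes (residual)
Rand index vs planted modules: 1.000
```

The simulated map has 847 nodes (348 species, 499 reactions) and 998 edges.
The two planted directed cycles (7 and 8 species, hence 14 and 16 nodes
after reaction expansion) are recovered exactly as the two centre SCCs; each
becomes one module core, the periphery attaches to the module it was grown
from, and the three planted off-bow-tie chains plus four isolated species
end up in the residual module.  The Rand index of 1.0 says the recovered
partition matches the planted one pair-for-pair.  `analysis/03_topology.py`
prints the map-level statistic row:

```
Network Node Edge Comp  Nei Path Dia   Den   Din  Dout  Rin Rout
   Main  847  998    9 2.36 8.75  24 0.003 2.051 2.435 0.89 0.96
```

i.e. a sparse (density 0.003), scale-free-looking map with in/out-degree
exponents near 2–2.5 — the statistical regime of curated disease maps.
`analysis/04_tissues.py` and `analysis/05_enrichment.py` continue with the
tissue overlap matrix and the planted-term enrichment (flagged at
Bonferroni and FDR ≤ 0.01).

## Layout

```
src/bowtiemap/     library: model, graphio, bowtie, cycles, modules,
                   topology, tissue, enrichment, synth, pipeline, cli
analysis/          numbered narrative drivers writing under results/
tests/             pytest suite incl. oracle-backed acceptance tests
docs/methods.md    model assumptions, conventions, defaults, limitations
```
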