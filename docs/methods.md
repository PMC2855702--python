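# Methods

`bowtiemap` analyses directed molecular interaction maps in which chemical
species alternate with explicit reaction nodes.  This note records the models
and procedures the package implements, the defaults and why they were chosen,
and what the synthetic generator does and does not emulate.

## Graph model

Nodes are either *species* (protein, gene, RNA, antisense RNA, simple
molecule, ion or complex; annotated with a compartment, state modifications
and tissue tags) or *reactions* (`re`-prefixed ids; state transition,
transcription, translation, transport, association, dissociation, or the two
"known/unknown transition" placeholders).  Edges are directed and typed
(reactant, product, regulator, or `plain` for species-level arcs imported
from SIF).  A reversible transition is represented by two directed arcs, one
per direction.  Duplicate (source, target, role, relation) edges collapse to
one; self-loops are kept but flagged.

`expand_reactions` rewrites every direct species→species arc as
species→reaction→species with a fresh reaction node, one node per arc (so a
reciprocal pair yields two reaction nodes).  After expansion no edge joins
two species, and two interacting species sit at directed distance exactly 2.
A consequence accepted here is that the clustering coefficient is not a
meaningful statistic for expanded maps, and the package does not compute it.

Complexes are modelled as single species nodes carrying a member-id set; they
are never expanded into their members.

## Bow-tie decomposition

The centre is the union of all non-trivial strongly connected components
(size ≥ 2, plus self-loop singletons, which are cycles of length 1).  IN is
every node with a directed path into the centre; OUT is every node reachable
from the centre that is not already IN; everything else (tendrils, tubes,
off-bow-tie components) is OTHER.  With several disjoint centre SCCs a node
can both reach and be reached by the centre union without lying in any SCC
(it sits on a tube from one centre SCC to another); the IN-before-OUT
precedence classifies such nodes as IN.  SCC extraction is delegated to
networkx (Tarjan-equivalent); a brute-force mutual-reachability oracle backs
it in the tests.

## Relevant cycles

A *relevant cycle* is a cycle that belongs to at least one minimum cycle
basis of the GF(2) cycle space — equivalently, one that cannot be written as
a symmetric-difference sum of strictly shorter cycles.  The cycle space is
taken on the undirected projection of each centre SCC (antiparallel arcs
collapse to one edge, self-loops are dropped); edge weights are uniformly 1,
so cycle weight is length.

The implementation enumerates all simple cycles of the projection and
applies the graded test directly: processing cycles in non-decreasing length,
a cycle is relevant iff it is independent (over GF(2), Gaussian elimination
on edge-incidence bit vectors) of the span of all strictly shorter cycles.
This is exact.  A Horton-style candidate construction from single
shortest-path trees was rejected because with tied shortest paths it can miss
relevant cycles; the exhaustive route is preferred for correctness and is
cheap at the scale of interaction-map SCCs, whose cyclomatic numbers are
small.  The cost is exponential in the cyclomatic number in the worst case,
which is the documented limitation.  Output order is deterministic: by
length, then by the lexicographically canonical node walk.

An independent oracle in the test suite re-derives the union of all minimum
cycle bases by matroid greedy search (an element lies in some minimum-weight
basis iff forcing it into the greedy basis does not raise the total weight)
and the two routes are compared on an exhaustive battery of small graphs.

## Module assembly

Cycles sharing strictly more than half of their nodes merge; the denominator
is the smaller cycle's size by default (a short cycle nested in a long one
should merge), with `max` and `union` available.  Merging is transitive via
connected components of the pairwise overlap graph, which makes the result
order-independent.  Cores are numbered by descending size.

Periphery (every node outside all cores — IN, OUT, OTHER, and centre nodes
not covered by any relevant cycle, e.g. two-node SCCs whose projection is
acyclic) is attached by weakly connected components: a component joins the
core it touches; if it touches several, the core linked by the most component
nodes wins, ties go to the largest core, remaining ties to the lowest module
id.  Nodes in no attached component form the residual module, reported with
its weak-component and isolated-node counts.  Every node therefore belongs to
exactly one module in the membership table (a node inside two overlapping
cores is tabulated under the lower module id).

## Topology statistics

* density = 2E/(N(N−1)); this undirected-style convention is the one that
  reproduces printed density values from (N, E) pairs across every
  module/tissue scale the package mirrors, whereas E/(N(N−1)) does not;
* mean neighbours = average number of *distinct* adjacent nodes, either
  direction, reciprocal pairs counted once, self-loops excluded — hence it
  equals 2E/N exactly when no reciprocal pairs or parallel arcs exist;
* shortest-path mean/variance/diameter over ordered reachable pairs only
  (unreachable pairs are excluded, not imputed), which keeps the statistics
  finite on multi-component maps;
* degree distributions use raw (degree, frequency) points, zero-degree nodes
  excluded; the power-law fit is OLS of log10 frequency on log10 degree,
  with γ = −slope and the regression R².  Fits with fewer than two distinct
  positive degrees are reported as `na`;
* hubs are species nodes (never reaction nodes) whose chosen degree strictly
  exceeds a threshold (default out-degree > 3; the threshold is a parameter
  because different map scales warrant different cut-offs).

Report rows are printed with round-half-up formatting (3 decimals for
density and exponents, 2 for neighbour/path means) in the fixed column order
Node, Edge, Comp, Nei, Path, Dia, Den, Din, Dout, Rin, Rout.

## Tissue sub-maps

A sub-map for tag T is induced by the species tagged T plus each reaction
node all of whose species participants are tagged T (a reaction cannot run
in a tissue missing a participant; an `any`-participant relaxation exists).
The overlap matrix counts species carrying both tags; untagged species are
in no sub-map.  Shared species are classified by their species-level
neighbourhoods — species reachable within two steps through reaction nodes —
so that reaction-node identities, which legitimately differ between
sub-maps, cannot cause spurious disagreement.  Nodes isolated in every
containing sub-map are a sub-class of "identical" in summary counts.

## Enrichment

One-sided hypergeometric tail per term, with the annotated part of the query
as the draw count ("List Total" convention).  Bonferroni multiplies by the
number of tested terms — by default terms with at least one query member —
and FDR is Benjamini–Hochberg step-up; a term is flagged significant when
both adjusted values are ≤ α (default 0.01).  This is a standard
over-representation test, not a re-implementation of any particular web
tool's proprietary score variant, so published p-values produced by such
tools are not reproduction targets.  The discrete test is conservative; the
null calibration in the tests uses margins dense enough (background 500,
term 40, query 104) that the attained type-I rate at 0.05 stays within
binomial 99% bounds.

## Synthetic generator

The generator emulates the statistical shape of a curated disease map:
default 348 species whose compartments (cytoplasm 248 : membrane 44 :
nucleus 21 : extracellular 25 : mitochondrion 4 : cytosol 1 : ER 4 : golgi 1)
and entity classes (protein 273 : gene 58 : RNA 46 : small molecule 5 :
ion 1 : antisense RNA 1) follow census-like proportions, reaction types
drawn the same way (state transition 160 : transcription 47 : …), five
tissue tags with mostly single-tag species, ~10% two-tag and rare three-tag
sharing, and an expanded size of roughly 300–850 nodes at default settings.

Structure: two planted directed cycles of 6–9 species (optionally sharing a
directed arc — sharing a fraction f of the shorter cycle produces a theta
graph whose faces overlap by 2s−1 of 2L nodes after reaction expansion);
periphery grown one species at a time, each new node drawing its out-degree
from a truncated discrete power law (target exponent 2.5, cap 12) and
attaching to existing nodes preferentially by in-degree, with 30% of nodes
instead attached as pure sinks.  New nodes are sources and sinks have no
out-edges, so the graph is acyclic outside the planted cycles and the
planted cycles are exactly the non-trivial SCCs — the recovery tests depend
on this.  Periphery attaches within the module of its first target, so
planted modules are disjoint subsystems; real maps have sparse cross-module
links that the method resolved by majority assignment, and the generator
deliberately omits them, which is why perfect recovery on synthetic fixtures
does not imply perfect recovery on real maps.  One planted hub is raised to
out-degree 10.  Three small chains and four isolated species are planted off
the bow tie as the residual ground truth.

Exact exponent control is not attempted: the contract is tolerance-based
recovery (fitted γ within ±0.4 of the target at 2000 species), and the
truncated-power-law draw with preferential wiring meets it; sink attachment
adds a mild downward bias that stays inside the tolerance.

Annotations: 20 random terms (each species included with probability 0.08)
plus one planted term whose inclusion probability inside planted module 1 is
multiplied by a fold factor (default 10, capped at 1); fold 1 makes the
planted term indistinguishable from the random ones, which is the null
calibration input.

All randomness flows through one `numpy.random.Generator` seeded from the
config; exports are byte-identical across runs for a fixed seed.

## What the tests do and do not show

The synthetic fixtures have clean planted structure (disjoint modules,
DAG periphery, exact power-law draws).  Passing tests demonstrate the
correctness of the algorithms and conventions on networks with that
statistical shape — not that a re-curated real map would decompose into any
particular number of modules, since that depends on the curation itself.

## Problem sizes used

Default analyses and tests run at 60–500 species; the exponent-recovery
checks use 2000 species; the cycle oracle battery uses graphs up to 9 nodes
and 14 edges (where exhaustive minimum-basis search is feasible); the
hypergeometric brute-force battery covers all margins with background ≤ 60.
These sizes were chosen so each check runs in seconds while staying in the
regime the corresponding statistic is used at.
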