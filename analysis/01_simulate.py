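#!/usr/bin/env python
"""Generate the default synthetic interaction map used by every later step.

Emits a SIF network, node attributes, annotation terms and the planted
ground truth under results/simulated/.
"""

from pathlib import Path

from bowtiemap.pipeline import run_simulate

OUT = Path(__file__).resolve().parents[1] / "results" / "simulated"
SEED = 1


def main() -> None:
    res = run_simulate(OUT, seed=SEED)
    g, truth = res["graph"], res["truth"]
    print(f"wrote fixture bundle to {OUT}")
    print(f"  nodes: {g.node_count} ({len(g.species_ids())} species, "
          f"{len(g.reaction_ids())} reactions), edges: {g.edge_count}")
    print(f"  planted cycles: {[len(c) for c in truth.planted_cycles]} species"
          f" each; merged by construction: {truth.cycles_merged}")
    print(f"  planted hubs: {truth.planted_hubs}")


if __name__ == "__main__":
    main()
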