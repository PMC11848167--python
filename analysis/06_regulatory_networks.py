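"""Build the phenotype-specific signed GRN over the male-specific DEGs.

Filters the prior interaction table (mechanism + brain tissue), Booleanizes
the DEGs from their direction of change, selects a consistent subnetwork by
genetic algorithm (inferring unknown signs), and ranks perturbagens and key
mediators.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import common

from sexdim.grn import (GAParams, booleanize, filter_interactions,
                        mediator_scores, perturbagen_scores, run_ga,
                        upstream_subnetwork, write_sif)
from sexdim.io import write_table


def main() -> None:
    data = common.load_data()
    patterns = common.load_patterns()
    filtered = filter_interactions(data["prior"])
    degs = set(patterns.loc[patterns["category"] == "male_specific", "feature"])
    cand = filtered[filtered["source"].isin(degs)
                    & filtered["target"].isin(degs)].reset_index(drop=True)
    if not len(cand):
        print("no candidate interactions among male-specific DEGs")
        return
    nodes = sorted(set(cand["source"]) | set(cand["target"]))
    states = booleanize(patterns, nodes, lfc_col="logfc_m")
    params = GAParams(population_size=100, max_generations=120,
                      stagnation_limit=25, seed=common.SEED)
    grn = run_ga(cand, states, params)
    write_table(grn.edges, common.RESULTS / "grn_selected_edges.tsv",
                provenance={"stage": "grn", "fitness": grn.fitness})
    pert = perturbagen_scores(grn)
    med = mediator_scores(grn)
    write_table(pert, common.RESULTS / "grn_perturbagens.tsv",
                provenance={"stage": "grn"})
    write_table(med, common.RESULTS / "grn_mediators.tsv",
                provenance={"stage": "grn"})

    explained = sum(sum(v.values()) for v in grn.explained.values())
    targets = len(grn.explained["AD"])
    print(f"candidate edges: {len(cand)} over {len(nodes)} DEGs; "
          f"selected {len(grn.edges)} (fitness {grn.fitness:.3f}, "
          f"{explained}/{2 * targets} target-phenotype states explained)")
    if len(pert):
        print(f"top perturbagen: {pert.iloc[0]['gene']} "
              f"({pert.iloc[0]['downstream_targets']} downstream targets)")
    if len(med) and med.iloc[0]["mediator_score"] > 0:
        key = med.iloc[0]
        print(f"key mediator: {key['gene']} "
              f"({key['n_upstream']} upstream x {key['n_downstream']} downstream)")
        sub = upstream_subnetwork(grn, key["gene"])
        write_sif(sub, common.RESULTS / "grn_mediator_upstream.sif")


if __name__ == "__main__":
    main()
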