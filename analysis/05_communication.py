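"""Ligand-receptor communication filtering around the male-specific DEGs.

Keeps pairs whose ligand and receptor are expressed in > 10% of the focal
cell type's cells and that touch a male-specific DEG, ranks candidate
ligands by downstream DEG reachability in the prior network, and runs
pathway enrichment of the retained endpoints at nominal p < 0.05.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
import common

from sexdim.comm import (comm_enrichment, filter_expressed, intersect_degs_lr,
                         rank_ligands)
from sexdim.io import write_table


def main() -> None:
    data = common.load_data()
    patterns = common.load_patterns()
    ct = common.FOCAL_CELL_TYPE
    expressed = filter_expressed(data["counts"], data["meta"], ct,
                                 common.EXPR_FRAC)
    degs = set(patterns.loc[patterns["category"] == "male_specific", "feature"])
    pairs = intersect_degs_lr(degs, data["lr"], expressed, expressed)
    write_table(pairs, common.RESULTS / "comm_pairs.tsv",
                provenance={"stage": "comm"})
    ligands = rank_ligands(pairs, data["prior"], degs)
    write_table(ligands, common.RESULTS / "comm_ligands.tsv",
                provenance={"stage": "comm"})
    endpoints = set(pairs["ligand"]) | set(pairs["receptor"])
    universe = sorted(
        set(pd.read_csv(common.RESULTS / f"de_{ct}_M.tsv", sep="\t",
                        comment="#")["gene"]))
    enr = comm_enrichment(endpoints, data["gene_sets"], universe)
    write_table(enr, common.RESULTS / "comm_enrichment.tsv",
                provenance={"stage": "comm"})
    print(f"{len(expressed)} genes expressed in > "
          f"{common.EXPR_FRAC:.0%} of {ct} cells")
    print(f"{len(pairs)} candidate pairs touch a male-specific DEG; "
          f"{len(enr)} pathways at nominal p < 0.05")
    if len(ligands):
        best = ligands.iloc[0]
        print(f"top ligand {best['ligand']}: reaches {best['score']} DEGs "
              f"downstream in the prior network")


if __name__ == "__main__":
    main()
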