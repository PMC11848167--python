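"""Cross-validate the transcriptomic sex patterns at the protein level.

Fits per-sex age-adjusted moderated-t models on the synthetic proteomics
table (which shares a subset of planted effects with the count matrix),
classifies proteins into the same sex categories, and intersects them with
the gene-level patterns per category.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import common

from sexdim.io import write_table
from sexdim.proteomics import classify_proteins, intersect_omics, run_dep


def main() -> None:
    data = common.load_data()
    patterns = common.load_patterns()
    dep = {}
    for sex in ("M", "F"):
        dep[sex] = run_dep(data["prot"], data["samples"], sex)
        write_table(dep[sex], common.RESULTS / f"dep_{sex}.tsv",
                    provenance={"stage": "proteomics", "sex": sex})
        n_sig = (dep[sex]["adj_p"] < common.FDR).sum()
        print(f"proteomics {sex}: {len(dep[sex])} proteins, "
              f"{n_sig} significant at FDR < {common.FDR}")
    dep_patterns = classify_proteins(dep["M"], dep["F"])
    write_table(dep_patterns, common.RESULTS / "dep_patterns.tsv",
                provenance={"stage": "proteomics"})
    overlap = intersect_omics({common.FOCAL_CELL_TYPE: patterns}, dep_patterns)
    write_table(overlap, common.RESULTS / "omics_overlap.tsv",
                provenance={"stage": "proteomics"})
    for row in overlap.itertuples(index=False):
        print(f"{row.category}: {row.n_overlap} concordant feature(s) "
              f"({row.overlap or '-'})")


if __name__ == "__main__":
    main()
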