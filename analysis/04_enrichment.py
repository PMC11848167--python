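"""Over-representation analysis of the sex-specific gene lists.

Tests the male- and female-specific DEG lists against the gene-set
collection (which contains one planted male-specific set among random
background sets), then applies the term-level sex-specificity rule.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
import common

from sexdim.enrich import enrich_collection, sex_specific_terms
from sexdim.io import write_table


def main() -> None:
    data = common.load_data()
    patterns = common.load_patterns()
    universe = sorted(
        set(pd.read_csv(common.RESULTS / f"de_{common.FOCAL_CELL_TYPE}_M.tsv",
                        sep="\t", comment="#")["gene"])
        | set(pd.read_csv(common.RESULTS / f"de_{common.FOCAL_CELL_TYPE}_F.tsv",
                          sep="\t", comment="#")["gene"])
    )
    enr = {}
    for sex, label in (("M", "male_specific"), ("F", "female_specific")):
        query = set(patterns.loc[patterns["category"] == label, "feature"])
        enr[sex] = enrich_collection(query, data["gene_sets"], universe)
        write_table(enr[sex], common.RESULTS / f"enrich_{label}.tsv",
                    provenance={"stage": "enrich", "category": label})
        top = enr[sex].iloc[0] if len(enr[sex]) else None
        if top is not None:
            print(f"{label}: top term {top['term']} "
                  f"(k={top['k']}/{top['K']}, adj p={top['adj_p']:.2e})")
    labeled = sex_specific_terms(enr["M"], enr["F"], common.FDR, common.NONSIG_P)
    write_table(labeled, common.RESULTS / "enrich_sex_specific.tsv",
                provenance={"stage": "enrich"})
    print("term labels:", labeled["label"].value_counts().to_dict())


if __name__ == "__main__":
    main()
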