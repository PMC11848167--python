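"""Per-sex AD-vs-control differential expression in the focal cell type.

Runs the Poisson-GLM likelihood-ratio test separately for male and female
astrocytes and reports how many genes pass FDR < 0.05 with |ln FC| > 0.25 in
each sex.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import common

from sexdim.de import run_de
from sexdim.io import write_table


def main() -> None:
    data = common.load_data()
    ct = common.FOCAL_CELL_TYPE
    for sex in ("M", "F"):
        res = run_de(data["counts"], data["meta"], ct, sex,
                     min_pct=common.EXPR_FRAC)
        sig = ((res["adj_p"] < common.FDR)
               & (res["logfc"].abs() > common.MIN_LFC)).sum()
        write_table(res, common.RESULTS / f"de_{ct}_{sex}.tsv",
                    provenance={"stage": "de", "cell_type": ct, "sex": sex})
        print(f"{ct} {sex}: {len(res)} genes tested, {sig} significant "
              f"(FDR < {common.FDR}, |ln FC| > {common.MIN_LFC})")


if __name__ == "__main__":
    main()
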