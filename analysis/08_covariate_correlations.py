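"""Sex-stratified Spearman correlations of DEG expression with covariates.

Collapses the focal cell type to per-subject pseudobulk and correlates the
planted genes' expression with age, Braak stage, and MMSE within each sex.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import common

from sexdim.covariates import correlate_covariates, pseudobulk
from sexdim.io import write_table


def main() -> None:
    data = common.load_data()
    pb = pseudobulk(data["counts"], data["meta"], common.FOCAL_CELL_TYPE)
    planted_genes = [e.gene for e in data["truth"].effects]
    corr = correlate_covariates(pb, data["subjects"], genes=planted_genes)
    write_table(corr, common.RESULTS / "covariate_correlations.tsv",
                provenance={"stage": "correlate"})
    sig = corr[corr["adj_p"] < common.FDR]
    print(f"{len(corr)} gene x covariate x sex correlations; "
          f"{len(sig)} significant at FDR < {common.FDR}")
    for cov in ("braak", "mmse", "age"):
        block = sig[sig["covariate"] == cov]
        if len(block):
            strongest = block.loc[block["rho"].abs().idxmax()]
            print(f"  strongest {cov}: {strongest['gene']} "
                  f"({strongest['sex']}) rho = {strongest['rho']:+.2f}")


if __name__ == "__main__":
    main()
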