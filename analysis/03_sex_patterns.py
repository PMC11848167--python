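"""Classify genes into sex-neutral / sex-specific / sex-dimorphic patterns.

Joins the two per-sex DE tables, applies the category rules, and scores the
classification against the planted ground truth.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
import common

from sexdim.io import write_table
from sexdim.patterns import (Thresholds, category_counts, classify_all,
                             summarize_patterns)


def main() -> None:
    ct = common.FOCAL_CELL_TYPE
    de = {}
    for sex in ("M", "F"):
        path = common.RESULTS / f"de_{ct}_{sex}.tsv"
        if not path.exists():
            raise SystemExit("run analysis/02_differential_expression.py first")
        de[sex] = pd.read_csv(path, sep="\t", comment="#")
    th = Thresholds(common.FDR, common.MIN_LFC, common.NONSIG_P)
    patterns = classify_all(de["M"], de["F"], th)
    write_table(patterns, common.RESULTS / f"patterns_{ct}.tsv",
                provenance={"stage": "classify"})
    write_table(summarize_patterns(patterns), common.RESULTS / "top_degs.tsv",
                provenance={"stage": "classify"})

    print("category counts:")
    print(category_counts(patterns).to_string())

    truth = common.load_data()["truth"]
    want = {"neutral": "sex_neutral", "male_specific": "male_specific",
            "female_specific": "female_specific", "dimorphic": "sex_dimorphic"}
    table = patterns.set_index("feature")
    hits = {c: 0 for c in want}
    for eff in truth.effects:
        if eff.gene in table.index and \
                table.loc[eff.gene, "category"] == want[eff.category]:
            hits[eff.category] += 1
    per = common.PLANTED_PER_CATEGORY
    print("planted-category recovery: " +
          ", ".join(f"{c}: {hits[c]}/{per}" for c in want))


if __name__ == "__main__":
    main()
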