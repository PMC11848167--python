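"""Simulate the synthetic study: cohort, counts, gene sets, networks, proteomics.

Generates a four-group sex-stratified cohort (toy scale), a sparse count
matrix with planted sex-neutral / sex-specific / sex-dimorphic AD effects in
astrocytes, background + planted gene sets, a partially signed prior
regulatory network containing a consistent planted chain, ligand-receptor
pairs, and a proteomics table sharing the first planted effects. Everything
is written as plain text under results/data, with the planted structure in
ground_truth.json.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
import common

from sexdim import synthetic as syn
from sexdim.io import write_counts, write_gmt, write_table
from sexdim.pipeline import PipelineConfig, simulate_study


def main(seed: int = common.SEED) -> None:
    cfg = PipelineConfig(seed=seed)
    (subjects, counts, meta, truth, gene_sets, prior, lr, prot,
     samples) = simulate_study(cfg)

    out = common.DATA
    out.mkdir(parents=True, exist_ok=True)
    write_table(subjects, out / "subjects.tsv")
    write_counts(counts, out / "counts.mtx", out / "genes.tsv", out / "cells.tsv")
    write_table(meta, out / "cell_meta.tsv")
    write_gmt(gene_sets, out / "gene_sets.gmt")
    write_table(prior, out / "prior_edges.tsv")
    write_table(lr, out / "lr_pairs.tsv")
    write_table(prot.reset_index(), out / "proteomics.tsv")
    write_table(samples, out / "proteomics_samples.tsv")
    truth.to_json(out / "ground_truth.json")

    n_ad = (subjects["condition"] == "AD").sum()
    print(f"cohort: {len(subjects)} subjects ({n_ad} AD), "
          f"{counts.shape[1]} cells x {counts.shape[0]} genes")
    print(f"planted effects: {len(truth.effects)} genes in "
          f"{common.FOCAL_CELL_TYPE} at |ln FC| = {common.DELTA_LOGFC}")
    print(f"written to {out}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else common.SEED)
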