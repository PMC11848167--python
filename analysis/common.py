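"""Shared paths and study conditions for the numbered analysis scripts.

The scripts run the stages of the sex-stratified analysis in order on a
synthetic cohort with planted effects; each reads the artifacts written by
the earlier stages from results/data and writes its own tables under
results/. Run them in numeric order, or `python analysis/run_all.py`.
"""

from pathlib import Path

REPO = Path(__file__).resolve().parent.parent
DATA = REPO / "results" / "data"
RESULTS = REPO / "results"

SEED = 0

# toy-scale study conditions: 12 subjects per (group, sex) in each of the
# four Braak-staged groups, 50 cells/subject over 3 cell types, 500 genes,
# planted |ln FC| = 0.8 effects (10 genes per sex category) in astrocytes
FOCAL_CELL_TYPE = "astrocytes"
CELL_TYPES = ("astrocytes", "excitatory_neurons", "microglia")
N_GENES = 500
PLANTED_PER_CATEGORY = 10
DELTA_LOGFC = 0.8

FDR = 0.05
MIN_LFC = 0.25
NONSIG_P = 0.1
EXPR_FRAC = 0.10


def load_data():
    """Read the artifacts written by 01_simulate_data.py."""
    import json

    import pandas as pd

    from sexdim.io import (CELL_META_SCHEMA, EDGE_SCHEMA, LR_SCHEMA,
                           SUBJECT_SCHEMA, read_counts, read_gmt, read_table)
    from sexdim.synthetic import GroundTruth

    if not (DATA / "counts.mtx").exists():
        raise SystemExit("run analysis/01_simulate_data.py first")
    counts = read_counts(DATA / "counts.mtx", DATA / "genes.tsv", DATA / "cells.tsv")
    meta = read_table(DATA / "cell_meta.tsv", CELL_META_SCHEMA)
    subjects = read_table(DATA / "subjects.tsv", SUBJECT_SCHEMA)
    gene_sets = read_gmt(DATA / "gene_sets.gmt")
    prior = read_table(DATA / "prior_edges.tsv", EDGE_SCHEMA)
    lr = read_table(DATA / "lr_pairs.tsv", LR_SCHEMA)
    prot = pd.read_csv(DATA / "proteomics.tsv", sep="\t").set_index("protein")
    samples = pd.read_csv(DATA / "proteomics_samples.tsv", sep="\t")
    truth = GroundTruth.from_json(DATA / "ground_truth.json")
    return dict(counts=counts, meta=meta, subjects=subjects,
                gene_sets=gene_sets, prior=prior, lr=lr, prot=prot,
                samples=samples, truth=truth)


def load_patterns():
    import pandas as pd

    path = RESULTS / f"patterns_{FOCAL_CELL_TYPE}.tsv"
    if not path.exists():
        raise SystemExit("run analysis/03_sex_patterns.py first")
    return pd.read_csv(path, sep="\t", comment="#")
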