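import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from sexdim import synthetic as syn
from sexdim import de as de_mod
from sexdim.patterns import Thresholds, classify_all


RECOVERY_SEED = 0
PLANTED_PER_CATEGORY = 10
DELTA_LOGFC = 0.8


def planted_study(seed: int = RECOVERY_SEED, delta: float = DELTA_LOGFC,
                  n_genes: int = 2000, cells_per_subject: int = 50,
                  subjects_per_stratum: int = 10, dispersion: float = 0.0):
    """One-cell-type cohort with 10 planted genes per category.

    10 subjects x 50 cells per (sex, condition) stratum = 500 cells per
    stratum per condition, the scale at which planted effects of |logFC| 0.8
    should be recovered. Poisson counts (dispersion 0) so the DE model is
    correctly specified.
    """
    spec = syn.CohortSpec(
        group_sizes={
            "control": (subjects_per_stratum, subjects_per_stratum),
            "late_ad": (subjects_per_stratum, subjects_per_stratum),
        },
        braak_ranges={"control": (), "late_ad": (5, 6)},
    )
    subjects = syn.generate_cohort(spec, seed=seed)
    genes = [f"G{i:04d}" for i in range(n_genes)]
    k = PLANTED_PER_CATEGORY
    planted = {
        "neutral": genes[0:k],
        "male_specific": genes[k:2 * k],
        "female_specific": genes[2 * k:3 * k],
        "dimorphic": genes[3 * k:4 * k],
    }
    effects = syn.make_effects(planted, "neurons", delta)
    counts, meta, truth = syn.generate_counts(
        subjects, cells_per_subject, genes, ["neurons"], effects,
        dispersion=dispersion, seed=seed + 1,
    )
    return counts, meta, truth, planted


@pytest.fixture(scope="session")
def recovery_run():
    """DE + classification of the planted study; shared across tests."""
    counts, meta, truth, planted = planted_study()
    de_m = de_mod.run_de(counts, meta, "neurons", "M")
    de_f = de_mod.run_de(counts, meta, "neurons", "F")
    patterns = classify_all(de_m, de_f, Thresholds())
    return {
        "counts": counts, "meta": meta, "truth": truth, "planted": planted,
        "de_m": de_m, "de_f": de_f, "patterns": patterns,
    }


@pytest.fixture
def tiny_counts():
    """4 genes x 6 cells with hand-checkable entries."""
    from sexdim.io import CountMatrix
    import scipy.sparse as sp

    mat = np.array(
        [
            [0, 1, 0, 2, 0, 3],
            [5, 5, 5, 5, 5, 5],
            [0, 0, 0, 0, 0, 0],
            [1, 0, 0, 0, 0, 0],
        ]
    )
    genes = ["GA", "GB", "GC", "GD"]
    cells = [f"c{i}" for i in range(6)]
    return CountMatrix(genes, cells, sp.csr_matrix(mat))


@pytest.fixture
def tiny_meta():
    return pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(6)],
            "subject_id": ["s1", "s1", "s2", "s2", "s3", "s3"],
            "cell_type": ["astro"] * 6,
            "condition": ["AD", "AD", "AD", "HC", "HC", "HC"],
            "sex": ["M"] * 6,
            "braak": [5, 5, 6, np.nan, np.nan, np.nan],
            "age": [80, 80, 85, 90, 90, 75],
            "mmse": [12, 12, 15, 28, 28, 25],
        }
    )
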