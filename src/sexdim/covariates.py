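"""Sex-stratified Spearman correlation of expression with clinical covariates.

Per-cell counts are first collapsed to a per-subject pseudobulk summary (mean
size-factor-normalized expression over the subject's cells of one cell type)
so each subject contributes one observation — correlating per-cell values
against a per-subject covariate would pseudoreplicate. Spearman's rho uses
mid-ranks for ties; p-values come from the t approximation with n - 2
degrees of freedom, with an exact permutation option for very small n.
Braak stage is treated ordinally (stages I..VI as 1..6) and controls, which
carry no stage, are excluded from Braak correlations.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
import scipy.stats

from .de import bh_adjust, size_factors
from .io import CountMatrix


def pseudobulk(
    counts: CountMatrix,
    meta: pd.DataFrame,
    cell_type: str,
    min_cells: int = 3,
    cell_size_factors: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-subject mean normalized expression for one cell type.

    Returns a subjects x genes table. Subjects with fewer than ``min_cells``
    cells of the type are dropped with a warning. Size factors default to the
    within-cell-type total-count/median normalization.
    """
    mask = (meta["cell_type"] == cell_type).to_numpy()
    if mask.sum() == 0:
        raise ValueError(f"cell type {cell_type!r} has no cells")
    sub = counts.counts[:, mask]
    sub_meta = meta.loc[mask].reset_index(drop=True)
    sf = size_factors(sub) if cell_size_factors is None else \
        np.asarray(cell_size_factors, dtype=float)[mask]
    norm = sub.multiply(1.0 / sf).tocsc()

    rows = {}
    for subject, idx in sub_meta.groupby("subject_id").groups.items():
        idx = np.asarray(idx)
        if len(idx) < min_cells:
            warnings.warn(
                f"subject {subject!r}: only {len(idx)} {cell_type!r} cells; dropped"
            )
            continue
        rows[subject] = np.asarray(norm[:, idx].mean(axis=1)).ravel()
    if not rows:
        raise ValueError(f"no subject has >= {min_cells} cells of type {cell_type!r}")
    out = pd.DataFrame.from_dict(rows, orient="index", columns=counts.genes)
    out.index.name = "subject_id"
    return out.sort_index()


def spearman(x, y, exact: bool = False) -> tuple[float, float]:
    """Spearman rho with mid-rank ties; p from the t approximation.

    With ``exact=True`` (n <= 10 only) the p-value is the two-sided
    permutation tail P(|rho_perm| >= |rho|) over all n! orderings.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("inputs must have equal length >= 3")
    rx = scipy.stats.rankdata(x)
    ry = scipy.stats.rankdata(y)
    if np.var(rx) == 0 or np.var(ry) == 0:
        warnings.warn("zero rank variance; rho undefined")
        return float("nan"), float("nan")
    if exact:
        n = len(x)
        if n > 10:
            raise ValueError("exact permutation p only supported for n <= 10")
        rho = float(np.corrcoef(rx, ry)[0, 1])
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            r = float(np.corrcoef(rx, np.asarray(perm))[0, 1])
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
            total += 1
        return rho, count / total
    res = scipy.stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def correlate_covariates(
    expr: pd.DataFrame,
    subjects: pd.DataFrame,
    genes=None,
    covariates=("age", "braak", "mmse"),
    stratify_by_sex: bool = True,
) -> pd.DataFrame:
    """Gene x covariate (x sex) Spearman correlations with BH per block.

    ``expr`` is a subjects x genes pseudobulk table; ``subjects`` carries the
    per-subject covariates. Missing covariate values (e.g. Braak for
    controls) are excluded pairwise; a covariate with fewer than 3 informative
    subjects in a block is skipped with a warning.
    """
    genes = list(expr.columns) if genes is None else [g for g in genes if g in expr.columns]
    meta = subjects.set_index("subject_id").loc[expr.index]
    sexes = ("M", "F") if stratify_by_sex else ("all",)
    blocks = []
    for sex in sexes:
        sel = np.ones(len(meta), dtype=bool) if sex == "all" else (meta["sex"] == sex).to_numpy()
        for covariate in covariates:
            if covariate not in meta.columns:
                warnings.warn(f"covariate {covariate!r} missing; skipped")
                continue
            cov = meta[covariate].to_numpy(dtype=float)
            ok = sel & ~np.isnan(cov)
            if ok.sum() < 3:
                warnings.warn(
                    f"covariate {covariate!r}, sex {sex!r}: fewer than 3 subjects; skipped"
                )
                continue
            rows = []
            for gene in genes:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    rho, p = spearman(expr[gene].to_numpy()[ok], cov[ok])
                rows.append(
                    {"gene": gene, "covariate": covariate, "sex": sex,
                     "rho": rho, "p": p, "n": int(ok.sum())}
                )
            block = pd.DataFrame(rows)
            defined = ~block["p"].isna()
            block["adj_p"] = np.nan
            if defined.any():
                block.loc[defined, "adj_p"] = bh_adjust(block.loc[defined, "p"].to_numpy())
            blocks.append(block)
    if not blocks:
        raise ValueError("no covariate block could be computed")
    return pd.concat(blocks, ignore_index=True)[
        ["gene", "covariate", "sex", "rho", "p", "n", "adj_p"]
    ]
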