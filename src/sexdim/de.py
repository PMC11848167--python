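"""Per-stratum AD-vs-control differential expression.

The test is a Poisson GLM likelihood-ratio test per gene: log-link, intercept
plus a condition indicator, with each cell's log size factor entering as a
fixed offset (the exposure). For this two-group design the maximum-likelihood
rates have closed form (group rate = group count total / group exposure
total), so the deviance

    D = 2 [ Y_AD ln r_AD + Y_HC ln r_HC - Y ln r_0 ]

(with 0 ln 0 := 0) is computed analytically and compared to chi-squared with
one degree of freedom. Multiple testing uses Benjamini-Hochberg within the
stratum over the genes actually tested.

Log fold changes are reported on the natural-log scale by default (the scale
on which the conventional 0.25 effect-size floor is defined), as
ln((mean normalized AD expression + pseudocount) / (HC counterpart +
pseudocount)).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix


class StratumError(ValueError):
    """A (cell type, sex) stratum cannot support the requested comparison."""


def size_factors(counts: sp.spmatrix, cell_mask: np.ndarray | None = None) -> np.ndarray:
    """Per-cell total counts divided by their median.

    Cells with zero totals get size factor 1 so their log offset stays finite;
    they contribute no counts to either group total and therefore cannot
    dominate a fit.
    """
    sub = counts if cell_mask is None else counts[:, cell_mask]
    totals = np.asarray(sub.sum(axis=0)).ravel().astype(float)
    med = np.median(totals[totals > 0]) if (totals > 0).any() else 1.0
    sf = totals / med
    sf[sf == 0] = 1.0
    return sf


def pct_expressed(counts_row: np.ndarray, cell_mask: np.ndarray) -> float:
    """Fraction of the selected cells with a nonzero count."""
    mask = np.asarray(cell_mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("cell mask selects no cells")
    row = np.asarray(counts_row).ravel()
    return float((row[mask] > 0).mean())


def compute_logfc(
    counts_row: np.ndarray,
    mask_ad: np.ndarray,
    mask_hc: np.ndarray,
    size_factors: np.ndarray,
    pseudocount: float = 0.01,
    base: float = np.e,
) -> float:
    """Log ratio of mean size-factor-normalized counts, AD over HC."""
    mask_ad = np.asarray(mask_ad, dtype=bool)
    mask_hc = np.asarray(mask_hc, dtype=bool)
    if mask_ad.sum() == 0 or mask_hc.sum() == 0:
        raise ValueError("both condition masks must select at least one cell")
    sf = np.asarray(size_factors, dtype=float)
    if (sf <= 0).any():
        raise ValueError("size factors must be positive")
    row = np.asarray(counts_row, dtype=float).ravel()
    norm = row / sf
    mean_ad = norm[mask_ad].mean()
    mean_hc = norm[mask_hc].mean()
    return float(np.log((mean_ad + pseudocount) / (mean_hc + pseudocount)) / np.log(base))


def _xlogy(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """x * log(y) with the 0 * log(0) := 0 convention."""
    out = np.zeros_like(np.asarray(x, dtype=float))
    pos = np.asarray(x) > 0
    out[pos] = np.asarray(x)[pos] * np.log(np.asarray(y)[pos])
    return out


def poisson_deviances(
    y_ad: np.ndarray, y_hc: np.ndarray, t_ad: float, t_hc: float
) -> np.ndarray:
    """Vectorized two-group Poisson LRT deviances from group totals.

    ``y_ad``/``y_hc`` are per-gene count sums over the AD / HC cells;
    ``t_ad``/``t_hc`` the corresponding exposure (size-factor) totals.
    """
    y_ad = np.asarray(y_ad, dtype=float)
    y_hc = np.asarray(y_hc, dtype=float)
    y_tot = y_ad + y_hc
    t_tot = t_ad + t_hc
    dev = 2.0 * (
        _xlogy(y_ad, y_ad / t_ad)
        + _xlogy(y_hc, y_hc / t_hc)
        - _xlogy(y_tot, y_tot / t_tot)
    )
    return np.maximum(dev, 0.0)  # clip fp noise at the null


def poisson_lrt(
    counts_row: np.ndarray,
    condition_labels: np.ndarray,
    offsets: np.ndarray | None = None,
) -> tuple[float, float]:
    """LRT of the condition effect for one gene; returns (p, deviance).

    ``condition_labels`` is boolean (True = AD); ``offsets`` are log size
    factors (zeros when omitted). An all-zero row yields the degenerate
    (p = 1, deviance = 0) result.
    """
    y = np.asarray(counts_row, dtype=float).ravel()
    lab = np.asarray(condition_labels, dtype=bool)
    if lab.all() or (~lab).all():
        raise ValueError("both conditions must be represented")
    t = np.exp(np.zeros_like(y) if offsets is None else np.asarray(offsets, dtype=float))
    dev = float(
        poisson_deviances(
            np.array([y[lab].sum()]), np.array([y[~lab].sum()]),
            float(t[lab].sum()), float(t[~lab].sum()),
        )[0]
    )
    p = float(chi2.sf(dev, df=1)) if dev > 0 else 1.0
    return p, dev


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_de(
    counts: CountMatrix,
    meta: pd.DataFrame,
    cell_type: str,
    sex: str,
    min_pct: float = 0.1,
    min_cells: int = 3,
    pseudocount: float = 0.01,
    logfc_base: float = np.e,
) -> pd.DataFrame:
    """AD-vs-HC differential expression within one (cell type, sex) stratum.

    Genes expressed in fewer than ``min_pct`` of cells in both conditions are
    excluded before testing; BH correction runs across the tested genes of
    this stratum only. Rows are sorted by adjusted p, then |logFC| descending,
    then gene symbol.
    """
    stratum = (meta["cell_type"] == cell_type) & (meta["sex"] == sex)
    mask_ad = (stratum & (meta["condition"] == "AD")).to_numpy()
    mask_hc = (stratum & (meta["condition"] == "HC")).to_numpy()
    n_ad, n_hc = int(mask_ad.sum()), int(mask_hc.sum())
    if n_ad < min_cells or n_hc < min_cells:
        raise StratumError(
            f"stratum (cell_type={cell_type!r}, sex={sex!r}) has {n_ad} AD and "
            f"{n_hc} HC cells; need >= {min_cells} per condition"
        )
    both = mask_ad | mask_hc
    sf_local = size_factors(counts.counts, both)
    # map stratum-local size factors back onto the full cell axis
    sf_full = np.ones(counts.shape[1])
    sf_full[both] = sf_local

    sub_ad = counts.counts[:, mask_ad]
    sub_hc = counts.counts[:, mask_hc]
    pct_ad = np.asarray((sub_ad > 0).sum(axis=1)).ravel() / n_ad
    pct_hc = np.asarray((sub_hc > 0).sum(axis=1)).ravel() / n_hc
    tested = np.maximum(pct_ad, pct_hc) >= min_pct

    y_ad = np.asarray(sub_ad.sum(axis=1)).ravel().astype(float)
    y_hc = np.asarray(sub_hc.sum(axis=1)).ravel().astype(float)
    t_ad = float(sf_full[mask_ad].sum())
    t_hc = float(sf_full[mask_hc].sum())
    dev = poisson_deviances(y_ad[tested], y_hc[tested], t_ad, t_hc)
    p = chi2.sf(dev, df=1)
    p[dev == 0] = 1.0
    adj = bh_adjust(p)

    inv_sf = 1.0 / sf_full
    norm_ad = sub_ad[tested].multiply(inv_sf[mask_ad]).mean(axis=1)
    norm_hc = sub_hc[tested].multiply(inv_sf[mask_hc]).mean(axis=1)
    norm_ad = np.asarray(norm_ad).ravel()
    norm_hc = np.asarray(norm_hc).ravel()
    logfc = np.log((norm_ad + pseudocount) / (norm_hc + pseudocount)) / np.log(logfc_base)

    genes = np.asarray(counts.genes)[tested]
    res = pd.DataFrame(
        {
            "gene": genes,
            "logfc": logfc,
            "pct_ad": pct_ad[tested],
            "pct_hc": pct_hc[tested],
            "p": p,
            "adj_p": adj,
            "n_ad": n_ad,
            "n_hc": n_hc,
            "cell_type": cell_type,
            "sex": sex,
        }
    )
    res = res.sort_values(
        by=["adj_p", "logfc", "gene"],
        key=lambda s: -s.abs() if s.name == "logfc" else s,
        kind="mergesort",
    ).reset_index(drop=True)
    return res
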