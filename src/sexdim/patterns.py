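"""Classification of features into sex-dependent differential-expression patterns.

A feature (gene or protein) is *significant* in a sex when its adjusted p is
below the FDR threshold and its |logFC| exceeds the effect-size floor. The
categories form a partition:

* ``sex_neutral``     — significant in both sexes, same direction of change
* ``sex_dimorphic``   — significant in both sexes, opposite directions
* ``male_specific`` / ``female_specific`` — significant in exactly one sex
  while the other sex stays clearly non-significant (nominal p above the
  ``nonsig_p`` guard, 0.1 by default)
* ``ambiguous``       — significant in one sex but the other sex's nominal p
  falls inside (adjusted-significance, nonsig_p], i.e. too close to call; also
  used when one sex was never tested
* ``not_significant`` — significant in neither sex

The ``nonsig_p`` guard is deliberately stricter than "not significant at
0.05": it prevents genes hovering around the threshold in the other sex from
being promoted to sex-specific calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CATEGORIES = (
    "sex_neutral",
    "male_specific",
    "female_specific",
    "sex_dimorphic",
    "ambiguous",
    "not_significant",
)


@dataclass(frozen=True)
class Thresholds:
    fdr: float = 0.05
    min_lfc: float = 0.25
    nonsig_p: float = 0.1

    def __post_init__(self) -> None:
        for name in ("fdr", "nonsig_p"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.min_lfc < 0:
            raise ValueError("min_lfc must be >= 0")


def classify_feature(
    male: dict | None,
    female: dict | None,
    thresholds: Thresholds = Thresholds(),
) -> str:
    """Assign one category from per-sex stats dicts with keys logfc, p, adj_p.

    A sex with no stats (feature filtered out or untested there) is treated
    as evidence-absent: a significant other sex then yields ``ambiguous``,
    never a specific call.
    """
    th = thresholds

    def significant(stats: dict | None) -> bool:
        if stats is None:
            return False
        return stats["adj_p"] < th.fdr and abs(stats["logfc"]) > th.min_lfc

    sig_m, sig_f = significant(male), significant(female)
    if sig_m and sig_f:
        same = np.sign(male["logfc"]) == np.sign(female["logfc"])
        return "sex_neutral" if same else "sex_dimorphic"
    if sig_m or sig_f:
        other = female if sig_m else male
        if other is None:
            return "ambiguous"
        if other["p"] > th.nonsig_p:
            return "male_specific" if sig_m else "female_specific"
        return "ambiguous"
    return "not_significant"


def classify_all(
    male_res: pd.DataFrame,
    female_res: pd.DataFrame,
    thresholds: Thresholds = Thresholds(),
    feature_col: str = "gene",
) -> pd.DataFrame:
    """Classify every feature in the union of two per-sex DE result tables.

    Returns one row per feature with both sexes' stats (NA where untested),
    the category, and a ``tested_one_sex_only`` flag.
    """
    m = male_res.set_index(feature_col)
    f = female_res.set_index(feature_col)
    features = sorted(set(m.index) | set(f.index))
    rows = []
    for feat in features:
        ms = m.loc[feat].to_dict() if feat in m.index else None
        fs = f.loc[feat].to_dict() if feat in f.index else None
        category = classify_feature(ms, fs, thresholds)
        rows.append(
            {
                "feature": feat,
                "category": category,
                "logfc_m": ms["logfc"] if ms else np.nan,
                "p_m": ms["p"] if ms else np.nan,
                "adj_p_m": ms["adj_p"] if ms else np.nan,
                "logfc_f": fs["logfc"] if fs else np.nan,
                "p_f": fs["p"] if fs else np.nan,
                "adj_p_f": fs["adj_p"] if fs else np.nan,
                "tested_one_sex_only": ms is None or fs is None,
            }
        )
    cols = ["feature", "category", "logfc_m", "p_m", "adj_p_m",
            "logfc_f", "p_f", "adj_p_f", "tested_one_sex_only"]
    return pd.DataFrame(rows, columns=cols)


def category_counts(table: pd.DataFrame) -> pd.Series:
    """Per-category feature counts over all six categories (zeros included)."""
    counts = table["category"].value_counts()
    return pd.Series({c: int(counts.get(c, 0)) for c in CATEGORIES})


def summarize_patterns(table: pd.DataFrame, top_k: int = 10) -> pd.DataFrame:
    """Top-k features per category by max |logFC| across sexes.

    Ties break by smaller minimum adjusted p, then feature symbol — the
    ordering used for the headline per-cell-type DEG tables.
    """
    if table.empty:
        return table.copy()
    work = table.copy()
    work["max_abs_lfc"] = np.nanmax(
        np.abs(work[["logfc_m", "logfc_f"]].to_numpy(dtype=float)), axis=1
    )
    work["min_adj_p"] = np.nanmin(
        work[["adj_p_m", "adj_p_f"]].to_numpy(dtype=float), axis=1
    )
    out = []
    for cat in CATEGORIES:
        block = work[work["category"] == cat]
        if block.empty:
            continue
        block = block.sort_values(
            by=["max_abs_lfc", "min_adj_p", "feature"],
            ascending=[False, True, True],
            kind="mergesort",
        ).head(top_k)
        out.append(block)
    return pd.concat(out, ignore_index=True) if out else work.iloc[0:0]
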