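"""Per-sex protein differential abundance with empirical-Bayes moderation.

Each protein is fit by ordinary least squares, abundance ~ intercept +
condition + age, separately within each sex; the condition coefficient is the
AD-vs-control effect adjusted for age at death. Residual variances are then
shrunk toward a common prior by the scaled-inverse-chi-squared empirical
Bayes scheme: hyperparameters (d0, s0^2) are estimated by a closed-form
method of moments on log s^2 (digamma/trigamma moments of the log
chi-squared distribution), the posterior variance of protein g is

    s2_post_g = (d0 * s0^2 + df * s2_g) / (d0 + df),

and the moderated t statistic uses s2_post with df + d0 degrees of freedom.
With d0 = 0 the pipeline reduces exactly to per-protein regression t-tests.

Proteins are classified into the same sex-dependent categories as genes,
with the effect sign playing the log-fold-change role and no effect-size
floor by default (abundance units differ from logFC units).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma
from scipy.stats import t as t_dist

from .de import bh_adjust
from .patterns import Thresholds, classify_all


def fit_protein_model(
    abundance_row,
    condition,
    age=None,
) -> tuple[float, float, int, float]:
    """OLS fit of one protein; returns (effect, se, residual df, s^2).

    ``condition`` is boolean (True = AD). Missing abundances are dropped
    (complete-case); at least 3 samples per condition must remain. If the age
    column is collinear with the rest of the design it is dropped with a
    warning.
    """
    y = np.asarray(abundance_row, dtype=float)
    cond = np.asarray(condition, dtype=bool)
    keep = ~np.isnan(y)
    y, cond = y[keep], cond[keep]
    age_v = None if age is None else np.asarray(age, dtype=float)[keep]
    if cond.sum() < 3 or (~cond).sum() < 3:
        raise ValueError("need >= 3 non-missing samples per condition")
    cols = [np.ones_like(y), cond.astype(float)]
    if age_v is not None:
        X_try = np.column_stack(cols + [age_v])
        if np.linalg.matrix_rank(X_try) < X_try.shape[1]:
            warnings.warn("age covariate collinear with design; dropped")
        else:
            cols.append(age_v)
    X = np.column_stack(cols)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    s2 = float(resid @ resid / df)
    xtx_inv = np.linalg.inv(X.T @ X)
    se = float(np.sqrt(s2 * xtx_inv[1, 1]))
    return float(beta[1]), se, df, s2


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (y > 0)."""
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = polygamma(1, y)
        step = tri * (1.0 - tri / x) / polygamma(2, y)
        y = y + step
        if abs(step) < 1e-10 * y:
            break
    return float(y)


def moderate_variances(
    s2,
    df: int,
    force_d0: float | None = None,
) -> tuple[np.ndarray, float, float]:
    """Empirical-Bayes variance shrinkage; returns (posterior s^2, d0, s0^2).

    Hyperparameters come from the method of moments on z = log s^2: under a
    scaled inverse-chi-squared prior, z has mean log s0^2 + [digamma(df/2) -
    log(df/2)] - [digamma(d0/2) - log(d0/2)] and excess variance
    trigamma(d0/2) beyond the sampling term trigamma(df/2). ``force_d0``
    overrides estimation (0 disables moderation entirely).
    """
    s2 = np.asarray(s2, dtype=float)
    if (s2 <= 0).sum() == len(s2) or len(s2) < 2:
        raise ValueError("need >= 2 proteins with positive s^2")
    pos = s2 > 0
    z = np.log(s2[pos])
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    if force_d0 is not None:
        d0 = float(force_d0)
        if d0 == 0:
            return s2.copy(), 0.0, float(np.exp(e.mean()))
        s02 = float(np.exp(e.mean() + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        evar = float(np.var(e, ddof=1))
        excess = evar - float(polygamma(1, df / 2.0))
        if np.var(s2[pos]) == 0:
            # identical variances: infinite prior df, posterior = common value
            return np.full_like(s2, s2[pos][0]), np.inf, float(s2[pos][0])
        if excess <= 0:
            d0 = np.inf
            s02 = float(np.exp(e.mean()))
            return np.full_like(s2, s02), d0, s02
        d0 = 2.0 * _trigamma_inverse(excess)
        s02 = float(np.exp(e.mean() + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    post = (d0 * s02 + df * s2) / (d0 + df)
    return post, float(d0), s02


def run_dep(
    abundance: pd.DataFrame,
    sample_meta: pd.DataFrame,
    sex: str,
    force_d0: float | None = None,
) -> pd.DataFrame:
    """Moderated-t AD-vs-control differential abundance within one sex.

    ``abundance`` is proteins x samples; ``sample_meta`` must carry
    subject_id, condition, sex, age. Returns a table with columns protein,
    logfc (the age-adjusted AD-control effect), t, p, adj_p, df_total.
    """
    meta = sample_meta[sample_meta["sex"] == sex]
    samples = [s for s in abundance.columns if s in set(meta["subject_id"])]
    meta = meta.set_index("subject_id").loc[samples]
    cond = (meta["condition"] == "AD").to_numpy()
    age = meta["age"].to_numpy(dtype=float)
    sub = abundance[samples]

    effects, ses, dfs, s2s, proteins = [], [], [], [], []
    for protein, row in sub.iterrows():
        try:
            eff, se, df, s2 = fit_protein_model(row.to_numpy(), cond, age)
        except ValueError:
            continue
        proteins.append(protein)
        effects.append(eff)
        ses.append(se)
        dfs.append(df)
        s2s.append(s2)
    if not proteins:
        raise ValueError(f"no protein could be fit for sex {sex!r}")
    dfs_arr = np.asarray(dfs)
    df_common = int(dfs_arr.min())  # conservative common df if missingness varies
    s2_arr = np.asarray(s2s)
    post, d0, _ = moderate_variances(s2_arr, df_common, force_d0=force_d0)
    se_arr = np.asarray(ses) * np.sqrt(post / s2_arr)
    t_stat = np.asarray(effects) / se_arr
    df_total = df_common + (d0 if np.isfinite(d0) else 0.0)
    if np.isinf(d0):
        from scipy.stats import norm

        p = 2 * norm.sf(np.abs(t_stat))
    else:
        p = 2 * t_dist.sf(np.abs(t_stat), df=df_total)
    res = pd.DataFrame(
        {
            "protein": proteins,
            "logfc": effects,
            "t": t_stat,
            "p": p,
            "adj_p": bh_adjust(p),
            "df_total": df_total,
            "sex": sex,
        }
    )
    return res.sort_values(["adj_p", "p", "protein"], kind="mergesort").reset_index(drop=True)


def classify_proteins(
    male_dep: pd.DataFrame,
    female_dep: pd.DataFrame,
    thresholds: Thresholds | None = None,
) -> pd.DataFrame:
    """Sex-pattern classification of proteins (no effect-size floor by default)."""
    th = thresholds if thresholds is not None else Thresholds(min_lfc=0.0)
    return classify_all(male_dep, female_dep, th, feature_col="protein")


def intersect_omics(
    deg_patterns: dict[str, pd.DataFrame],
    dep_patterns: pd.DataFrame,
    symbol_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per cell type x category overlap of DEGs with matching-category DEPs.

    ``symbol_map`` maps protein identifiers to gene symbols; unmapped
    proteins are reported in the ``unmapped`` column of a summary row rather
    than silently dropped.
    """
    if symbol_map is not None:
        mapped = dep_patterns.copy()
        mapped["feature"] = [
            symbol_map.get(p, p) for p in mapped["feature"]
        ]
        unmapped = sorted(
            p for p in dep_patterns["feature"] if p not in symbol_map
        )
    else:
        mapped = dep_patterns
        unmapped = []
    rows = []
    for cat in ("male_specific", "female_specific", "sex_dimorphic"):
        deps = set(mapped.loc[mapped["category"] == cat, "feature"])
        for cell_type, table in deg_patterns.items():
            degs = set(table.loc[table["category"] == cat, "feature"])
            overlap = sorted(degs & deps)
            rows.append(
                {
                    "cell_type": cell_type,
                    "category": cat,
                    "n_degs": len(degs),
                    "n_deps": len(deps),
                    "n_overlap": len(overlap),
                    "overlap": ",".join(overlap),
                    "unmapped": ",".join(unmapped),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["cell_type", "category", "n_degs", "n_deps", "n_overlap",
                 "overlap", "unmapped"],
    )
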