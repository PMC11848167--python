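"""Hypergeometric over-representation analysis with a sex-specificity layer.

For a query list of n genes drawn from a universe of N genes, a set with K
members in the universe, and an observed overlap of k genes, the enrichment
p-value is the exact hypergeometric upper tail P(X >= k). The universe is
the set of genes actually tested in the corresponding differential-expression
run (conditioning on testability), not the whole genome.

A term is called sex-specific at the term level under the same logic used for
genes: adjusted p below the FDR threshold in one sex with the other sex's
nominal p above the non-significance guard.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom

from .de import bh_adjust
from .io import GeneSetCollection


@dataclass
class EnrichmentResult:
    term: str
    k: int  # overlap
    K: int  # set size within universe
    n: int  # query size
    N: int  # universe size
    p: float
    overlap: list[str]

    def __post_init__(self) -> None:
        if self.k > min(self.K, self.n):
            raise ValueError("overlap exceeds set or query size")


def ora_test(query, term_set, universe) -> EnrichmentResult:
    """Exact hypergeometric upper-tail test of one term against one query."""
    universe = set(universe)
    if not universe:
        raise ValueError("universe is empty")
    query = set(query) & universe
    members = set(term_set) & universe
    overlap = sorted(query & members)
    N, K, n, k = len(universe), len(members), len(query), len(overlap)
    p = float(hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
    return EnrichmentResult("", k, K, n, N, min(p, 1.0), overlap)


def enrich_collection(
    query,
    collection: GeneSetCollection,
    universe,
    min_set: int = 5,
    max_set: int = 500,
) -> pd.DataFrame:
    """ORA of a query against every set in a collection, BH over tested sets.

    Sets whose universe-intersected size falls outside [min_set, max_set] are
    skipped. Rows are sorted by adjusted p then term name.
    """
    universe = set(universe)
    rows = []
    for name, members in collection.items():
        K = len(set(members) & universe)
        if not min_set <= K <= max_set:
            continue
        res = ora_test(query, members, universe)
        rows.append(
            {
                "term": name,
                "k": res.k,
                "K": res.K,
                "n": res.n,
                "N": res.N,
                "p": res.p,
                "overlap": ",".join(res.overlap),
            }
        )
    df = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p", "overlap"])
    if len(df):
        df["adj_p"] = bh_adjust(df["p"].to_numpy())
        df = df.sort_values(["adj_p", "p", "term"], kind="mergesort").reset_index(drop=True)
    else:
        df["adj_p"] = pd.Series(dtype=float)
    return df


def sex_specific_terms(
    male_enrich: pd.DataFrame,
    female_enrich: pd.DataFrame,
    fdr: float = 0.05,
    nonsig_p: float = 0.1,
) -> pd.DataFrame:
    """Label terms male_specific / female_specific / shared / unlabeled.

    A term absent from one sex's table (not tested there) is treated as
    nominal p = 1 in that sex and flagged.
    """
    m = male_enrich.set_index("term")
    f = female_enrich.set_index("term")
    terms = sorted(set(m.index) | set(f.index))
    rows = []
    for term in terms:
        in_m, in_f = term in m.index, term in f.index
        p_m = float(m.loc[term, "p"]) if in_m else 1.0
        adj_m = float(m.loc[term, "adj_p"]) if in_m else 1.0
        p_f = float(f.loc[term, "p"]) if in_f else 1.0
        adj_f = float(f.loc[term, "adj_p"]) if in_f else 1.0
        sig_m, sig_f = adj_m < fdr, adj_f < fdr
        if sig_m and sig_f:
            label = "shared"
        elif sig_m and p_f > nonsig_p:
            label = "male_specific"
        elif sig_f and p_m > nonsig_p:
            label = "female_specific"
        else:
            label = "unlabeled"
        rows.append(
            {
                "term": term,
                "label": label,
                "p_m": p_m,
                "adj_p_m": adj_m,
                "p_f": p_f,
                "adj_p_f": adj_f,
                "tested_one_sex_only": not (in_m and in_f),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["term", "label", "p_m", "adj_p_m", "p_f", "adj_p_f",
                 "tested_one_sex_only"],
    )
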