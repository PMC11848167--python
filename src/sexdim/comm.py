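"""Cell-cell communication filtering and ranking.

The communication layer works on ligand-receptor pairs: sender-cell ligands
and receiver-cell receptors must be expressed in more than a given fraction
of that cell type's cells (strictly greater than 10% by default), retained
pairs must touch at least one differentially expressed gene of the requested
sex category, and candidate ligands are ranked by their regulatory influence
— the number of DEGs reachable from the ligand by directed paths in the
prior regulatory network. Pathway enrichment of the retained pair endpoints
uses a nominal p < 0.05 filter.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

from .enrich import enrich_collection
from .io import CountMatrix, GeneSetCollection


def filter_expressed(
    counts: CountMatrix,
    meta: pd.DataFrame,
    cell_type: str,
    threshold: float = 0.10,
) -> set[str]:
    """Genes nonzero in strictly more than ``threshold`` of the type's cells."""
    mask = (meta["cell_type"] == cell_type).to_numpy()
    if mask.sum() == 0:
        raise ValueError(f"cell type {cell_type!r} has no cells")
    sub = counts.counts[:, mask]
    frac = np.asarray((sub > 0).sum(axis=1)).ravel() / mask.sum()
    return {g for g, fr in zip(counts.genes, frac) if fr > threshold}


def intersect_degs_lr(
    degs: set[str],
    lr: pd.DataFrame,
    expressed_sender: set[str],
    expressed_receiver: set[str],
) -> pd.DataFrame:
    """Ligand-receptor pairs expressed in their cell types and touching a DEG.

    The ligand must be expressed in the sender type, the receptor in the
    receiver type, and at least one endpoint must belong to ``degs``. DEG
    status of each endpoint is recorded. Output order follows the input
    table.
    """
    rows = []
    for pair in lr.itertuples(index=False):
        if pair.ligand not in expressed_sender:
            continue
        if pair.receptor not in expressed_receiver:
            continue
        lig_deg = pair.ligand in degs
        rec_deg = pair.receptor in degs
        if not (lig_deg or rec_deg):
            continue
        rows.append(
            {
                "ligand": pair.ligand,
                "receptor": pair.receptor,
                "ligand_is_deg": lig_deg,
                "receptor_is_deg": rec_deg,
            }
        )
    return pd.DataFrame(
        rows, columns=["ligand", "receptor", "ligand_is_deg", "receptor_is_deg"]
    )


def rank_ligands(
    pairs: pd.DataFrame,
    prior: pd.DataFrame,
    degs: set[str],
    top_n: int = 30,
) -> pd.DataFrame:
    """Rank candidate ligands by the number of DEGs reachable downstream.

    The score of a ligand is |{DEGs reachable from it by directed paths in
    the prior network}| (the ligand itself included when it is a DEG and
    reachable through a cycle is irrelevant — self is excluded). Ligands
    absent from the network score 0 and are flagged rather than dropped.
    """
    graph = nx.DiGraph()
    graph.add_edges_from(zip(prior["source"], prior["target"]))
    rows = []
    for ligand in sorted(set(pairs["ligand"])):
        if ligand in graph:
            reachable = nx.descendants(graph, ligand)
            score = len(reachable & degs)
            in_network = True
        else:
            score = 0
            in_network = False
        rows.append({"ligand": ligand, "score": score, "in_network": in_network})
    df = pd.DataFrame(rows, columns=["ligand", "score", "in_network"])
    df = df.sort_values(["score", "ligand"], ascending=[False, True],
                        kind="mergesort").reset_index(drop=True)
    return df.head(top_n)


def comm_enrichment(
    pair_endpoint_genes: set[str],
    collection: GeneSetCollection,
    universe,
    nominal_p: float = 0.05,
    min_set: int = 5,
    max_set: int = 500,
) -> pd.DataFrame:
    """Pathway ORA of the communication endpoints, filtered at nominal p."""
    if not pair_endpoint_genes:
        return enrich_collection(set(), collection, universe, min_set, max_set).iloc[0:0]
    res = enrich_collection(pair_endpoint_genes, collection, universe, min_set, max_set)
    return res[res["p"] < nominal_p].reset_index(drop=True)
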