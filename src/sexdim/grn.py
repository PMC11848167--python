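"""Phenotype-specific signed gene regulatory networks via a genetic algorithm.

Candidate regulatory interactions (a partially signed prior network over the
DEGs of one sex category) are filtered by mechanism and tissue, each DEG is
Booleanized from its direction of change (up in AD: state 1 in the AD
phenotype, 0 in control; down: the reverse), and a subnetwork is selected so
the retained signed edges *align* with the Boolean states of both phenotypes:

* an activating edge s -> t is consistent in phenotype phi iff
  B_phi(s) = B_phi(t);
* an inhibiting edge is consistent iff B_phi(s) != B_phi(t).

A target node (any node with at least one candidate incoming edge) counts as
*explained* in a phenotype when at least one selected incoming edge is
consistent there. The GA maximizes the explained fraction across both
phenotypes minus a parsimony penalty:

    fitness = (sum_phi #explained) / (2 #targets) - lambda * #selected/#candidate

The chromosome carries one inclusion bit per candidate edge plus one sign bit
per unknown-sign edge, so missing regulatory effects are deduced jointly with
edge selection. Selection is tournament-based with uniform crossover,
per-bit mutation, and elitism; the run is fully reproducible from its seed.

Downstream of the selected network, perturbagens are ranked by the number of
nodes reachable from them (their downstream regulatory influence) and the
*key mediator* maximizes |ancestors| x |descendants| — a node both heavily
regulated and heavily regulating.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .synthetic import ALLOWED_MECHANISMS


@dataclass
class BooleanStates:
    """Per-gene Boolean expression states; B_CTRL is the complement of B_AD."""

    b_ad: dict[str, int]

    def state(self, gene: str, phenotype: str) -> int:
        b = self.b_ad[gene]
        return b if phenotype == "AD" else 1 - b

    def genes(self):
        return self.b_ad.keys()


def filter_interactions(
    raw: pd.DataFrame,
    allowed_mechanisms=ALLOWED_MECHANISMS,
    tissue: str = "brain",
) -> pd.DataFrame:
    """Keep edges with an admissible mechanism and tissue; drop self-loops and
    duplicate (source, target, sign) rows."""
    allowed = set(allowed_mechanisms)
    keep = raw[
        raw["mechanism"].isin(allowed)
        & (raw["tissue"] == tissue)
        & (raw["source"] != raw["target"])
    ]
    return keep.drop_duplicates(subset=["source", "target", "sign"]).reset_index(drop=True)


def booleanize(de_table: pd.DataFrame, node_genes, lfc_col: str | None = None) -> BooleanStates:
    """Boolean states from DE log fold changes; every node must be a DEG.

    ``lfc_col`` selects the fold-change column (e.g. ``logfc_m`` on a
    sex-pattern table); defaults to ``logfc``.
    """
    col = "feature" if "feature" in de_table.columns else "gene"
    if lfc_col is None:
        lfc_col = "logfc" if "logfc" in de_table.columns else "logfc_m"
    lookup = de_table.set_index(col)[lfc_col].to_dict()
    states: dict[str, int] = {}
    for gene in node_genes:
        if gene not in lookup or pd.isna(lookup[gene]):
            raise ValueError(f"node {gene!r} has no differential-expression record")
        lfc = float(lookup[gene])
        if lfc == 0:
            raise ValueError(f"node {gene!r} has log fold change 0; not a DEG")
        states[gene] = 1 if lfc > 0 else 0
    return BooleanStates(states)


def edge_consistent(
    edge: tuple[str, str, int], states: BooleanStates, phenotype: str
) -> bool:
    """Alignment of one signed edge with the Boolean states of a phenotype."""
    source, target, sign = edge
    if sign not in (1, -1):
        raise ValueError(f"edge sign must be +1 or -1, got {sign!r}")
    same = states.state(source, phenotype) == states.state(target, phenotype)
    return same if sign == 1 else not same


@dataclass
class GAParams:
    population_size: int = 200
    max_generations: int = 500
    stagnation_limit: int = 50
    crossover_rate: float = 0.9
    mutation_rate: float | None = None  # default 1/L
    tournament_k: int = 3
    elitism: int = 2
    lambda_parsimony: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 1 or self.max_generations < 1:
            raise ValueError("population and generation counts must be >= 1")
        for name in ("crossover_rate",):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.mutation_rate is not None and not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation_rate must be in [0, 1]")


@dataclass
class PhenotypeGRN:
    """GA-selected consistent subnetwork with resolved signs."""

    edges: pd.DataFrame  # source, target, sign (+1/-1)
    fitness: float
    states: BooleanStates
    explained: dict[str, dict[str, bool]]  # phenotype -> target -> explained
    params: GAParams | None = None
    candidate_count: int = 0

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.states.genes())
        for e in self.edges.itertuples(index=False):
            g.add_edge(e.source, e.target, sign=int(e.sign))
        return g


class _CandidateArrays:
    """Flat arrays over candidate edges for fast fitness evaluation."""

    def __init__(self, candidate: pd.DataFrame, states: BooleanStates):
        if candidate.empty:
            raise ValueError("candidate network is empty")
        self.sources = candidate["source"].to_numpy()
        self.targets = candidate["target"].to_numpy()
        sign_raw = candidate["sign"].astype(str).to_numpy()
        self.known_sign = np.where(sign_raw == "+", 1, np.where(sign_raw == "-", -1, 0))
        self.unknown_idx = np.flatnonzero(self.known_sign == 0)
        self.n_edges = len(candidate)
        self.n_unknown = len(self.unknown_idx)

        target_names = sorted(set(self.targets))
        self.target_pos = {t: i for i, t in enumerate(target_names)}
        self.target_names = target_names
        self.edge_target = np.array([self.target_pos[t] for t in self.targets])

        b_s = np.array([states.b_ad[s] for s in self.sources])
        b_t = np.array([states.b_ad[t] for t in self.targets])
        same_ad = b_s == b_t
        # B_CTRL is the complement of B_AD for every node, so state equality —
        # hence per-edge consistency — is identical in both phenotypes.
        self.cons_plus = {"AD": same_ad, "CTRL": same_ad}
        self.cons_minus = {"AD": ~same_ad, "CTRL": ~same_ad}

    def edge_consistency(self, signs: np.ndarray, phenotype: str) -> np.ndarray:
        return np.where(
            signs == 1, self.cons_plus[phenotype], self.cons_minus[phenotype]
        )

    def resolve_signs(self, sign_bits: np.ndarray) -> np.ndarray:
        signs = self.known_sign.copy()
        signs[self.unknown_idx] = np.where(sign_bits == 1, 1, -1)
        return signs


def _fitness(
    include: np.ndarray,
    sign_bits: np.ndarray,
    arrays: _CandidateArrays,
    lam: float,
) -> float:
    signs = arrays.resolve_signs(sign_bits)
    n_targets = len(arrays.target_names)
    explained_total = 0
    for phenotype in ("AD", "CTRL"):
        cons = arrays.edge_consistency(signs, phenotype) & include.astype(bool)
        hit = np.zeros(n_targets, dtype=bool)
        np.logical_or.at(hit, arrays.edge_target, cons)
        explained_total += int(hit.sum())
    frac = explained_total / (2 * n_targets)
    return frac - lam * include.sum() / arrays.n_edges


def network_fitness(
    chromosome: tuple[np.ndarray, np.ndarray],
    candidate: pd.DataFrame,
    states: BooleanStates,
    lam: float = 0.0,
) -> float:
    """Fitness of one chromosome (edge inclusion bits, unknown-edge sign bits)."""
    include, sign_bits = chromosome
    arrays = _CandidateArrays(candidate, states)
    include = np.asarray(include, dtype=int)
    sign_bits = np.asarray(sign_bits, dtype=int)
    if len(include) != arrays.n_edges or len(sign_bits) != arrays.n_unknown:
        raise ValueError(
            f"chromosome lengths ({len(include)}, {len(sign_bits)}) do not match "
            f"candidate ({arrays.n_edges} edges, {arrays.n_unknown} unknown signs)"
        )
    return _fitness(include, sign_bits, arrays, lam)


def run_ga(
    candidate: pd.DataFrame,
    states: BooleanStates,
    params: GAParams = GAParams(),
) -> PhenotypeGRN:
    """Select a Boolean-consistent signed subnetwork by genetic algorithm."""
    arrays = _CandidateArrays(candidate, states)
    rng = np.random.default_rng(params.seed)
    n_bits = arrays.n_edges + arrays.n_unknown
    mut = params.mutation_rate if params.mutation_rate is not None else 1.0 / n_bits
    lam = params.lambda_parsimony
    pop = rng.integers(0, 2, size=(params.population_size, n_bits))

    def eval_pop(pop: np.ndarray) -> np.ndarray:
        return np.array(
            [
                _fitness(ind[: arrays.n_edges], ind[arrays.n_edges:], arrays, lam)
                for ind in pop
            ]
        )

    fit = eval_pop(pop)
    best_fit = fit.max()
    stagnant = 0
    for _ in range(params.max_generations):
        order = np.argsort(-fit, kind="mergesort")
        elite = pop[order[: params.elitism]].copy()
        n_children = params.population_size - params.elitism
        # tournament selection of parent pairs
        draws = rng.integers(0, params.population_size,
                             size=(2 * n_children, params.tournament_k))
        winners = draws[np.arange(2 * n_children), np.argmax(fit[draws], axis=1)]
        mothers, fathers = pop[winners[:n_children]], pop[winners[n_children:]]
        cross = rng.random(n_children) < params.crossover_rate
        swap_mask = rng.integers(0, 2, size=(n_children, n_bits)).astype(bool)
        children = np.where(cross[:, None] & swap_mask, fathers, mothers)
        flip = rng.random((n_children, n_bits)) < mut
        children = np.where(flip, 1 - children, children)
        pop = np.vstack([elite, children])
        fit = eval_pop(pop)
        if fit.max() > best_fit + 1e-12:
            best_fit = fit.max()
            stagnant = 0
        else:
            stagnant += 1
            if stagnant >= params.stagnation_limit:
                break

    best = pop[np.argmax(fit)]
    include = best[: arrays.n_edges].astype(bool)
    sign_bits = best[arrays.n_edges:]
    signs = arrays.resolve_signs(sign_bits)
    selected = candidate.loc[include, ["source", "target"]].copy()
    selected["sign"] = signs[include]
    selected = selected.reset_index(drop=True)

    explained: dict[str, dict[str, bool]] = {}
    for phenotype in ("AD", "CTRL"):
        cons = arrays.edge_consistency(signs, phenotype) & include
        hit = np.zeros(len(arrays.target_names), dtype=bool)
        np.logical_or.at(hit, arrays.edge_target, cons)
        explained[phenotype] = dict(zip(arrays.target_names, hit.tolist()))

    return PhenotypeGRN(
        edges=selected,
        fitness=float(fit.max()),
        states=states,
        explained=explained,
        params=params,
        candidate_count=arrays.n_edges,
    )


def greedy_baseline(
    candidate: pd.DataFrame, states: BooleanStates, lam: float = 0.01
) -> float:
    """Fitness of a greedy edge-addition baseline (GA must match or beat it)."""
    arrays = _CandidateArrays(candidate, states)
    signs = arrays.known_sign.copy()
    # greedy sign resolution: pick the sign that makes the edge consistent
    for i in arrays.unknown_idx:
        signs[i] = 1 if arrays.cons_plus["AD"][i] else -1
    include = np.zeros(arrays.n_edges, dtype=bool)
    current = _fitness(include.astype(int), (signs[arrays.unknown_idx] == 1).astype(int),
                       arrays, lam)
    improved = True
    while improved:
        improved = False
        best_gain, best_edge = 0.0, -1
        for e in range(arrays.n_edges):
            if include[e]:
                continue
            include[e] = True
            f = _fitness(include.astype(int),
                         (signs[arrays.unknown_idx] == 1).astype(int), arrays, lam)
            include[e] = False
            if f - current > best_gain + 1e-12:
                best_gain, best_edge = f - current, e
        if best_edge >= 0:
            include[best_edge] = True
            current += best_gain
            improved = True
    return current


def perturbagen_scores(grn: PhenotypeGRN) -> pd.DataFrame:
    """Per-node downstream influence: number of nodes reachable by directed paths."""
    g = grn.graph()
    rows = [
        {"gene": node, "downstream_targets": len(nx.descendants(g, node))}
        for node in g.nodes
    ]
    df = pd.DataFrame(rows, columns=["gene", "downstream_targets"])
    return df.sort_values(["downstream_targets", "gene"], ascending=[False, True],
                          kind="mergesort").reset_index(drop=True)


def mediator_scores(grn: PhenotypeGRN) -> pd.DataFrame:
    """Key-mediator ranking: |ancestors| x |descendants| per node."""
    g = grn.graph()
    rows = []
    for node in g.nodes:
        up = len(nx.ancestors(g, node))
        down = len(nx.descendants(g, node))
        rows.append(
            {"gene": node, "n_upstream": up, "n_downstream": down,
             "mediator_score": up * down}
        )
    df = pd.DataFrame(rows, columns=["gene", "n_upstream", "n_downstream",
                                     "mediator_score"])
    return df.sort_values(["mediator_score", "gene"], ascending=[False, True],
                          kind="mergesort").reset_index(drop=True)


def upstream_subnetwork(grn: PhenotypeGRN, gene: str) -> pd.DataFrame:
    """Edges among the ancestor closure of ``gene`` (upstream-regulator view)."""
    g = grn.graph()
    if gene not in g:
        raise KeyError(f"gene {gene!r} not in network")
    keep = nx.ancestors(g, gene) | {gene}
    edges = grn.edges
    mask = edges["source"].isin(keep) & edges["target"].isin(keep)
    return edges[mask].reset_index(drop=True)


def write_sif(edges: pd.DataFrame, path) -> None:
    lines = [
        f"{e.source}\t{'activates' if e.sign == 1 else 'inhibits'}\t{e.target}"
        for e in edges.itertuples(index=False)
    ]
    from pathlib import Path

    Path(path).write_text("".join(line + "\n" for line in lines))


def write_dot(edges: pd.DataFrame, path) -> None:
    from pathlib import Path

    body = "".join(
        f'  "{e.source}" -> "{e.target}" '
        f'[color={"green" if e.sign == 1 else "red"}];\n'
        for e in edges.itertuples(index=False)
    )
    Path(path).write_text("digraph grn {\n" + body + "}\n")
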