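import itertools

import numpy as np
import pandas as pd
import pytest

from sexdim.grn import (
    BooleanStates,
    GAParams,
    booleanize,
    edge_consistent,
    filter_interactions,
    greedy_baseline,
    mediator_scores,
    network_fitness,
    perturbagen_scores,
    run_ga,
    upstream_subnetwork,
    write_sif,
)


def random_instance(seed, n_nodes=6, n_edges=8):
    rng = np.random.default_rng(seed)
    nodes = [f"n{i}" for i in range(n_nodes)]
    states = BooleanStates({n: int(rng.integers(2)) for n in nodes})
    rows = []
    seen = set()
    while len(rows) < n_edges:
        s, t = rng.choice(nodes, 2, replace=False)
        if (s, t) in seen:
            continue
        seen.add((s, t))
        sign = ["+", "-", "unknown"][int(rng.integers(3))]
        rows.append({"source": s, "target": t, "sign": sign,
                     "mechanism": "binding", "tissue": "brain"})
    return pd.DataFrame(rows), states


def exhaustive_optimum(candidate, states, lam):
    """Best fitness over every chromosome (small instances only)."""
    n_edges = len(candidate)
    n_unknown = int((candidate["sign"] == "unknown").sum())
    best = -np.inf
    for inc in itertools.product((0, 1), repeat=n_edges):
        for sgn in itertools.product((0, 1), repeat=n_unknown):
            f = network_fitness((np.array(inc), np.array(sgn)), candidate,
                                states, lam)
            best = max(best, f)
    return best


class TestFilterInteractions:
    RAW = pd.DataFrame(
        {
            "source": ["a", "a", "b", "c", "c"],
            "target": ["b", "b", "b", "d", "c"],
            "sign": ["+", "+", "-", "+", "+"],
            "mechanism": ["binding", "binding", "phosphorylation",
                          "regulation", "binding"],
            "tissue": ["brain", "brain", "brain", "liver", "brain"],
        }
    )

    def test_mechanism_tissue_selfloop_duplicate_rules(self):
        out = filter_interactions(self.RAW)
        # duplicate a->b collapsed; phosphorylation removed; liver removed;
        # self-loop c->c removed
        assert len(out) == 1
        assert out.iloc[0]["source"] == "a" and out.iloc[0]["target"] == "b"


class TestBooleanize:
    DE = pd.DataFrame({"gene": ["up", "down"], "logfc": [0.5, -0.3]})

    def test_signs_map_to_states(self):
        states = booleanize(self.DE, ["up", "down"])
        assert states.state("up", "AD") == 1 and states.state("up", "CTRL") == 0
        assert states.state("down", "AD") == 0 and states.state("down", "CTRL") == 1

    def test_missing_record_and_zero_lfc_rejected(self):
        with pytest.raises(ValueError, match="no differential"):
            booleanize(self.DE, ["up", "absent"])
        zero = pd.DataFrame({"gene": ["g"], "logfc": [0.0]})
        with pytest.raises(ValueError, match="0"):
            booleanize(zero, ["g"])


class TestEdgeConsistent:
    STATES = BooleanStates({"s": 1, "t1": 1, "t0": 0})

    def test_activation_inhibition_semantics(self):
        assert edge_consistent(("s", "t1", 1), self.STATES, "AD")
        assert not edge_consistent(("s", "t1", -1), self.STATES, "AD")
        assert edge_consistent(("s", "t0", -1), self.STATES, "AD")

    def test_consistency_equal_in_both_phenotypes(self):
        # complementing every state preserves equality, so consistency matches
        for edge in (("s", "t1", 1), ("s", "t0", -1), ("s", "t1", -1)):
            assert edge_consistent(edge, self.STATES, "AD") == \
                edge_consistent(edge, self.STATES, "CTRL")

    def test_unknown_sign_rejected(self):
        with pytest.raises(ValueError):
            edge_consistent(("s", "t1", 0), self.STATES, "AD")


class TestNetworkFitness:
    def test_single_consistent_edge_reaches_one(self):
        cand = pd.DataFrame({"source": ["a"], "target": ["b"], "sign": ["+"]})
        states = BooleanStates({"a": 1, "b": 1})
        f = network_fitness((np.array([1]), np.array([], dtype=int)), cand,
                            states, lam=0.0)
        assert f == 1.0

    def test_no_edges_selected_is_zero(self):
        cand = pd.DataFrame({"source": ["a"], "target": ["b"], "sign": ["+"]})
        states = BooleanStates({"a": 1, "b": 1})
        f = network_fitness((np.array([0]), np.array([], dtype=int)), cand,
                            states, lam=0.0)
        assert f == 0.0

    def test_parsimony_penalty_subtracts(self):
        cand = pd.DataFrame({"source": ["a"], "target": ["b"], "sign": ["+"]})
        states = BooleanStates({"a": 1, "b": 1})
        f = network_fitness((np.array([1]), np.array([], dtype=int)), cand,
                            states, lam=0.25)
        assert f == pytest.approx(0.75)

    def test_permutation_equivariance(self):
        cand, states = random_instance(3)
        relabel = {n: f"x{n}" for n in states.b_ad}
        cand2 = cand.assign(source=cand["source"].map(relabel),
                            target=cand["target"].map(relabel))
        states2 = BooleanStates({relabel[n]: b for n, b in states.b_ad.items()})
        chrom = (np.ones(len(cand), dtype=int),
                 np.zeros(int((cand["sign"] == "unknown").sum()), dtype=int))
        assert network_fitness(chrom, cand, states, 0.01) == \
            pytest.approx(network_fitness(chrom, cand2, states2, 0.01))

    def test_chromosome_length_mismatch_rejected(self):
        cand, states = random_instance(0)
        with pytest.raises(ValueError):
            network_fitness((np.ones(2, dtype=int), np.array([], dtype=int)),
                            cand, states, 0.0)


SMALL_GA = GAParams(population_size=64, max_generations=120, stagnation_limit=25,
                    seed=0)


class TestRunGa:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_optimum_on_small_instances(self, seed):
        cand, states = random_instance(seed, n_nodes=6, n_edges=8)
        lam = 0.01
        params = GAParams(population_size=64, max_generations=120,
                          stagnation_limit=25, lambda_parsimony=lam, seed=seed)
        result = run_ga(cand, states, params)
        assert result.fitness == pytest.approx(
            exhaustive_optimum(cand, states, lam), abs=1e-12)

    def test_planted_consistent_subnetwork_fully_explained(self):
        # chain of activations among all-up genes is fully consistent
        genes = [f"g{i}" for i in range(6)]
        states = BooleanStates({g: 1 for g in genes})
        cand = pd.DataFrame({"source": genes[:-1], "target": genes[1:],
                             "sign": ["unknown"] * 5})
        result = run_ga(cand, states, SMALL_GA)
        explained_frac = np.mean(
            [list(result.explained[ph].values()) for ph in ("AD", "CTRL")])
        assert explained_frac == 1.0
        assert (result.edges["sign"] == 1).all()  # inferred signs

    def test_determinism(self):
        cand, states = random_instance(4, n_edges=10)
        a = run_ga(cand, states, SMALL_GA)
        b = run_ga(cand, states, SMALL_GA)
        pd.testing.assert_frame_equal(a.edges, b.edges)
        assert a.fitness == b.fitness

    @pytest.mark.parametrize("seed", range(4))
    def test_beats_or_matches_greedy_baseline(self, seed):
        cand, states = random_instance(seed + 100, n_nodes=7, n_edges=10)
        result = run_ga(cand, states, GAParams(
            population_size=64, max_generations=150, stagnation_limit=30,
            seed=seed))
        assert result.fitness >= greedy_baseline(cand, states, 0.01) - 1e-12

    @pytest.mark.parametrize("seed", range(4))
    def test_selected_unknown_signs_locally_optimal(self, seed):
        cand, states = random_instance(seed + 50, n_nodes=6, n_edges=9)
        lam = 0.01
        params = GAParams(population_size=64, max_generations=150,
                          stagnation_limit=30, lambda_parsimony=lam, seed=seed)
        result = run_ga(cand, states, params)
        key = cand.set_index(["source", "target"])["sign"]
        for i, edge in result.edges.iterrows():
            if key.loc[(edge["source"], edge["target"])] != "unknown":
                continue
            flipped = result.edges.copy()
            flipped.loc[i, "sign"] = -edge["sign"]
            base = _fitness_of_selection(result.edges, cand, states, lam)
            alt = _fitness_of_selection(flipped, cand, states, lam)
            assert alt <= base + 1e-12

    def test_empty_candidate_rejected(self):
        empty = pd.DataFrame(columns=["source", "target", "sign"])
        with pytest.raises(ValueError):
            run_ga(empty, BooleanStates({"a": 1}), SMALL_GA)


def _fitness_of_selection(selected, candidate, states, lam):
    """Fitness of a concrete signed edge selection, via the chromosome API."""
    sel = {(e.source, e.target): int(e.sign) for e in selected.itertuples(index=False)}
    include = np.array([
        1 if (e.source, e.target) in sel else 0
        for e in candidate.itertuples(index=False)
    ])
    sign_bits = []
    for e in candidate.itertuples(index=False):
        if e.sign == "unknown":
            chosen = sel.get((e.source, e.target), 1)
            sign_bits.append(1 if chosen == 1 else 0)
    return network_fitness((include, np.array(sign_bits, dtype=int)),
                           candidate, states, lam)


def _grn_from_edges(edge_list):
    from sexdim.grn import PhenotypeGRN

    edges = pd.DataFrame(edge_list, columns=["source", "target"])
    edges["sign"] = 1
    nodes = set(edges["source"]) | set(edges["target"])
    return PhenotypeGRN(edges=edges, fitness=1.0,
                        states=BooleanStates({n: 1 for n in nodes}),
                        explained={})


class TestNodeScores:
    def test_chain_perturbagen_counts(self):
        grn = _grn_from_edges([("a", "b"), ("b", "c")])
        scores = perturbagen_scores(grn).set_index("gene")["downstream_targets"]
        assert scores["a"] == 2 and scores["b"] == 1 and scores["c"] == 0

    def test_cycle_excludes_self(self):
        grn = _grn_from_edges([("a", "b"), ("b", "a")])
        scores = perturbagen_scores(grn).set_index("gene")["downstream_targets"]
        assert scores["a"] == 1 and scores["b"] == 1

    def test_chain_mediator_scores(self):
        grn = _grn_from_edges([("a", "b"), ("b", "c")])
        med = mediator_scores(grn).set_index("gene")["mediator_score"]
        assert med["b"] == 1 and med["a"] == 0 and med["c"] == 0

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_bfs_oracle_on_30_node_graphs(self, seed):
        def bfs(adj, start):
            seen, frontier = set(), [start]
            while frontier:
                for nxt in adj.get(frontier.pop(), ()):
                    if nxt not in seen:
                        seen.add(nxt)
                        frontier.append(nxt)
            seen.discard(start)
            return seen

        rng = np.random.default_rng(seed)
        nodes = [f"n{i}" for i in range(30)]
        edge_list = sorted({(nodes[i], nodes[j])
                            for i, j in rng.integers(0, 30, size=(60, 2)) if i != j})
        fwd, rev = {}, {}
        for s, t in edge_list:
            fwd.setdefault(s, set()).add(t)
            rev.setdefault(t, set()).add(s)
        grn = _grn_from_edges(edge_list)
        pert = perturbagen_scores(grn).set_index("gene")["downstream_targets"]
        med = mediator_scores(grn).set_index("gene")["mediator_score"]
        for node in pert.index:
            down = len(bfs(fwd, node))
            up = len(bfs(rev, node))
            assert pert[node] == down
            assert med[node] == up * down

    def test_upstream_subnetwork_and_sif_export(self, tmp_path):
        grn = _grn_from_edges([("a", "b"), ("b", "c"), ("d", "c"), ("c", "e")])
        sub = upstream_subnetwork(grn, "c")
        pairs = set(map(tuple, sub[["source", "target"]].values))
        assert pairs == {("a", "b"), ("b", "c"), ("d", "c")}
        write_sif(sub, tmp_path / "sub.sif")
        lines = (tmp_path / "sub.sif").read_text().splitlines()
        assert len(lines) == 3 and all("activates" in l for l in lines)
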