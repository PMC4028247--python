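import math

import networkx as nx
import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from orthokit.core_io_qc import SimilarityHit, qc_filter
from orthokit.orthogroups import (
    MclParams,
    OrthoGroup,
    build_graph,
    combine,
    evalue_to_weight,
    expand_in_paralogs,
    infer_paranoid,
    mcl,
    merge_pairwise_groups,
    normalize_weights,
    reciprocal_best_hits,
)
from orthokit.synthetic_data import SimulationConfig, simulate_proteomes, simulate_similarity


def hit(q, s, evalue):
    return SimilarityHit(query=q, subject=s, identity=90.0, aln_length=50,
                         evalue=evalue, bitscore=100.0)


def group_labels(groups):
    labels = {}
    for grp in groups:
        for pid, _ in grp.members:
            labels[pid] = grp.group_id
    return labels


# -- build_graph -------------------------------------------------------------

class TestBuildGraph:
    SPECIES = {"a1": "A", "b1": "B"}

    def test_weight_is_neg_log10(self):
        g = build_graph([hit("a1", "b1", 1e-5)], self.SPECIES, cutoff=1e-5)
        assert g.weight("a1", "b1") == pytest.approx(5.0)

    def test_zero_evalue_capped(self):
        g = build_graph([hit("a1", "b1", 0.0)], self.SPECIES)
        assert g.weight("a1", "b1") == pytest.approx(180.0)

    def test_above_cutoff_excluded(self):
        g = build_graph([hit("a1", "b1", 1e-3)], self.SPECIES, cutoff=1e-5)
        assert g.weight("a1", "b1") == 0.0

    def test_reciprocal_hits_averaged(self):
        hits = [hit("a1", "b1", 1e-10), hit("b1", "a1", 1e-20)]
        g = build_graph(hits, self.SPECIES)
        assert g.weight("a1", "b1") == pytest.approx(15.0)

    def test_self_hits_dropped(self):
        g = build_graph([hit("a1", "a1", 1e-50)], self.SPECIES)
        assert g.nx.number_of_edges() == 0

    def test_unknown_protein_raises(self):
        with pytest.raises(KeyError, match="zz"):
            build_graph([hit("a1", "zz", 1e-10)], self.SPECIES)

    def test_edge_category(self):
        species = {"a1": "A", "a2": "A", "b1": "B"}
        g = build_graph([hit("a1", "a2", 1e-10), hit("a1", "b1", 1e-10)], species)
        assert g.nx.edges["a1", "a2"]["category"] == "intra"
        assert g.nx.edges["a1", "b1"]["category"] == "inter"


# -- normalize_weights -------------------------------------------------------

class TestNormalizeWeights:
    def test_two_edge_stratum(self, make_graph):
        # weights {4, 8}, mean 6 -> {0.667, 1.333}
        g = make_graph(
            {"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
            [("a1", "b1", 4.0), ("a2", "b2", 8.0)],
        )
        out = normalize_weights(g)
        assert out.weight("a1", "b1") == pytest.approx(4 / 6)
        assert out.weight("a2", "b2") == pytest.approx(8 / 6)

    def test_single_edge_stratum_is_one(self, make_graph):
        g = make_graph({"a1": "A", "b1": "B"}, [("a1", "b1", 42.0)])
        assert normalize_weights(g).weight("a1", "b1") == pytest.approx(1.0)

    def test_all_equal_weights(self, make_graph):
        g = make_graph(
            {"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
            [("a1", "b1", 7.0), ("a1", "b2", 7.0), ("a2", "b1", 7.0)],
        )
        out = normalize_weights(g)
        for u, v in [("a1", "b1"), ("a1", "b2"), ("a2", "b1")]:
            assert out.weight(u, v) == pytest.approx(1.0)

    def test_strata_independent(self, make_graph):
        # intra-A edges normalized separately from inter A-B edges
        g = make_graph(
            {"a1": "A", "a2": "A", "b1": "B"},
            [("a1", "a2", 100.0), ("a1", "b1", 1.0)],
        )
        out = normalize_weights(g)
        assert out.weight("a1", "a2") == pytest.approx(1.0)
        assert out.weight("a1", "b1") == pytest.approx(1.0)


# -- mcl ---------------------------------------------------------------------

def mcl_oracle(weights: np.ndarray, inflation: float, prune: float = 1e-5,
               tol: float = 1e-6, iters: int = 100):
    """Independent brute-force flow iteration on a dense matrix."""
    m = weights.astype(float).copy()
    n = m.shape[0]
    loops = m.max(axis=0)
    loops[loops == 0] = 1.0
    m[np.diag_indices(n)] = loops

    def norm(x):
        s = x.sum(axis=0)
        s[s == 0] = 1.0
        return x / s

    m = norm(m)
    for _ in range(iters):
        prev = m
        m = norm(np.power(m @ m, inflation))
        m[m < prune] = 0.0
        m = norm(m)
        if np.abs(m - prev).max() < tol:
            break
    comp = nx.Graph()
    comp.add_nodes_from(range(n))
    comp.add_edges_from(zip(*np.nonzero(m)))
    return sorted(frozenset(c) for c in nx.connected_components(comp))


def triangle_edges(names, w=1.0):
    a, b, c = names
    return [(a, b, w), (b, c, w), (a, c, w)]


class TestMcl:
    def test_two_disconnected_triangles(self, make_graph):
        nodes = {n: "A" for n in "abc"} | {n: "B" for n in "xyz"}
        g = make_graph(nodes, triangle_edges("abc") + triangle_edges("xyz"))
        groups = mcl(g)
        assert len(groups) == 2
        assert {grp.protein_ids for grp in groups} == {
            frozenset("abc"), frozenset("xyz")
        }

    def test_isolated_node_singleton(self, make_graph):
        g = make_graph({"a": "A", "b": "A", "c": "A", "lone": "B"},
                       triangle_edges("abc"))
        groups = mcl(g)
        singles = [grp for grp in groups if len(grp.members) == 1]
        assert len(singles) == 1
        assert singles[0].protein_ids == frozenset({"lone"})

    def test_barbell_matches_oracle(self, make_graph):
        # two triangles joined by a weak bridge; inflation 2 separates them
        nodes = {n: "A" for n in "abc"} | {n: "B" for n in "xyz"}
        edges = triangle_edges("abc") + triangle_edges("xyz") + [("c", "x", 0.1)]
        g = make_graph(nodes, edges)
        order = sorted(nodes)
        idx = {n: i for i, n in enumerate(order)}
        w = np.zeros((6, 6))
        for u, v, weight in edges:
            w[idx[u], idx[v]] = w[idx[v], idx[u]] = weight
        expected = mcl_oracle(w, inflation=2.0)
        groups = mcl(g, MclParams(inflation=2.0))
        got = sorted(
            frozenset(idx[p] for p in grp.protein_ids) for grp in groups
        )
        assert got == expected
        assert len(groups) == 2

    def test_random_small_graphs_match_oracle(self, make_graph):
        rng = np.random.default_rng(42)
        for trial in range(20):
            n = int(rng.integers(2, 9))
            names = [f"n{i}" for i in range(n)]
            w = np.triu(rng.random((n, n)) * (rng.random((n, n)) < 0.5), k=1)
            w = w + w.T
            edges = [
                (names[i], names[j], w[i, j])
                for i in range(n) for j in range(i + 1, n) if w[i, j] > 0
            ]
            g = make_graph({name: "A" for name in names}, edges)
            groups = mcl(g, MclParams(inflation=2.0))
            got = sorted(
                frozenset(int(p[1:]) for p in grp.protein_ids) for grp in groups
            )
            assert got == mcl_oracle(w, inflation=2.0), f"trial {trial}"

    def test_output_partitions_nodes(self, make_graph):
        nodes = {f"p{i}": "A" for i in range(10)}
        rng = np.random.default_rng(7)
        edges = []
        names = sorted(nodes)
        for i in range(10):
            for j in range(i + 1, 10):
                if rng.random() < 0.3:
                    edges.append((names[i], names[j], float(rng.random())))
        groups = mcl(make_graph(nodes, edges))
        seen = [p for grp in groups for p in grp.protein_ids]
        assert sorted(seen) == names  # every node exactly once

    def test_never_merges_components(self, make_graph):
        nodes = {"a": "A", "b": "A", "x": "B", "y": "B"}
        groups = mcl(make_graph(nodes, [("a", "b", 1.0), ("x", "y", 1.0)]))
        for grp in groups:
            assert grp.protein_ids in (frozenset("ab"), frozenset("xy"))

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            MclParams(inflation=1.0)


# -- reciprocal_best_hits ----------------------------------------------------

class TestReciprocalBestHits:
    def test_single_pair(self, make_graph):
        g = make_graph({"a": "A", "b": "B"}, [("a", "b", 5.0)])
        pairs = reciprocal_best_hits(g, "A", "B")
        assert [(p.a, p.b) for p in pairs] == [("a", "b")]
        assert pairs[0].seed_weight == 5.0

    def test_best_partner_wins(self, make_graph):
        # exhaustive 2-edge case: a-b1 w5, a-b2 w7; b2's best is a
        g = make_graph({"a": "A", "b1": "B", "b2": "B"},
                       [("a", "b1", 5.0), ("a", "b2", 7.0)])
        pairs = reciprocal_best_hits(g, "A", "B")
        assert [(p.a, p.b) for p in pairs] == [("a", "b2")]

    def test_tie_breaks_lexicographic(self, make_graph):
        g = make_graph({"a": "A", "b1": "B", "b2": "B"},
                       [("a", "b1", 5.0), ("a", "b2", 5.0)])
        pairs = reciprocal_best_hits(g, "A", "B")
        assert [(p.a, p.b) for p in pairs] == [("a", "b1")]

    def test_no_cross_edges(self, make_graph):
        g = make_graph({"a": "A", "b": "B"}, [])
        assert reciprocal_best_hits(g, "A", "B") == []

    def test_same_species_rejected(self, make_graph):
        g = make_graph({"a": "A"}, [])
        with pytest.raises(ValueError):
            reciprocal_best_hits(g, "A", "A")


# -- expand_in_paralogs ------------------------------------------------------

class TestExpandInParalogs:
    def graph(self, make_graph, w_intra):
        return make_graph(
            {"a": "A", "a2": "A", "b": "B"},
            [("a", "b", 5.0), ("a", "a2", w_intra)],
        )

    def seed(self, g):
        return reciprocal_best_hits(g, "A", "B")[0]

    def test_stronger_in_paralog_added(self, make_graph):
        g = self.graph(make_graph, 7.0)
        grp = expand_in_paralogs(self.seed(g), g)
        assert grp.protein_ids == frozenset({"a", "a2", "b"})

    def test_weaker_in_paralog_excluded(self, make_graph):
        g = self.graph(make_graph, 4.0)
        grp = expand_in_paralogs(self.seed(g), g)
        assert grp.protein_ids == frozenset({"a", "b"})

    def test_equal_weight_boundary_added(self, make_graph):
        g = self.graph(make_graph, 5.0)
        grp = expand_in_paralogs(self.seed(g), g)
        assert "a2" in grp.protein_ids


# -- merge_pairwise_groups ---------------------------------------------------

def union_find_oracle(groups):
    """Independent union-find over member overlap."""
    parent = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for grp in groups:
        members = list(grp.members)
        for m in members:
            parent.setdefault(m, m)
        for m in members[1:]:
            parent[find(members[0])] = find(m)
    out = {}
    for m in parent:
        out.setdefault(find(m), set()).add(m)
    return sorted(frozenset(v) for v in out.values())


def pg(*pids, species="A"):
    return OrthoGroup(
        group_id="g" + "".join(pids),
        members=frozenset((p, species) for p in pids),
        source="paranoid",
    )


class TestMergePairwiseGroups:
    def test_shared_member_merges(self):
        merged = merge_pairwise_groups([pg("a", "b"), pg("b", "c")])
        assert len(merged) == 1
        assert merged[0].protein_ids == frozenset("abc")

    def test_disjoint_unchanged(self):
        merged = merge_pairwise_groups([pg("a", "b"), pg("c", "d")])
        assert sorted((grp.protein_ids for grp in merged), key=sorted) == [
            frozenset("ab"), frozenset("cd")
        ]

    def test_chain_matches_union_find_oracle(self):
        groups = [pg("a", "b"), pg("b", "c"), pg("c", "d")]
        merged = merge_pairwise_groups(groups)
        assert sorted(frozenset(grp.members) for grp in merged) == \
            union_find_oracle(groups)
        assert len(merged) == 1 and len(merged[0].members) == 4

    def test_output_disjoint(self):
        groups = [pg("a", "b"), pg("b", "c"), pg("x", "y"), pg("y", "z")]
        merged = merge_pairwise_groups(groups)
        seen = []
        for grp in merged:
            seen.extend(grp.members)
        assert len(seen) == len(set(seen))


# -- combine -----------------------------------------------------------------

def og_(gid, members, source):
    return OrthoGroup(group_id=gid, members=frozenset(members), source=source)


class TestCombine:
    def test_union_of_both_algorithms(self, make_graph):
        g = make_graph({"bait": "A", "x": "B", "y": "B"},
                       [("bait", "x", 5.0), ("bait", "y", 5.0)])
        mcl_set = [og_("m1", [("bait", "A"), ("x", "B")], "mcl")]
        par_set = [og_("p1", [("bait", "A"), ("y", "B")], "paranoid")]
        combined = combine(mcl_set, par_set, ["bait"], g)
        assert len(combined) == 1
        assert combined[0].protein_ids == frozenset({"bait", "x", "y"})

    def test_agreement_is_idempotent(self, make_graph):
        g = make_graph({"bait": "A", "x": "B"}, [("bait", "x", 5.0)])
        members = [("bait", "A"), ("x", "B")]
        combined = combine([og_("m1", members, "mcl")],
                           [og_("p1", members, "paranoid")], ["bait"], g)
        assert combined[0].members == frozenset(members)

    def test_conflict_resolved_by_weight(self, make_graph):
        # x co-grouped with bait1 (w=6) and bait2 (w=4) -> bait1 wins
        g = make_graph({"bait1": "A", "bait2": "A", "x": "B"},
                       [("bait1", "x", 6.0), ("bait2", "x", 4.0)])
        mcl_set = [og_("m1", [("bait1", "A"), ("x", "B")], "mcl"),
                   og_("m2", [("bait2", "A")], "mcl")]
        par_set = [og_("p1", [("bait2", "A"), ("x", "B")], "paranoid"),
                   og_("p2", [("bait1", "A")], "paranoid")]
        combined = combine(mcl_set, par_set, ["bait1", "bait2"], g)
        by_bait = {next(iter(grp.baits)): grp for grp in combined}
        assert "x" in by_bait["bait1"].protein_ids
        assert "x" not in by_bait["bait2"].protein_ids
        assert not by_bait["bait1"].ambiguous

    def test_conflict_tie_flagged_in_both(self, make_graph):
        g = make_graph({"bait1": "A", "bait2": "A", "x": "B"},
                       [("bait1", "x", 5.0), ("bait2", "x", 5.0)])
        mcl_set = [og_("m1", [("bait1", "A"), ("x", "B")], "mcl")]
        par_set = [og_("p1", [("bait2", "A"), ("x", "B")], "paranoid")]
        combined = combine(mcl_set, par_set, ["bait1", "bait2"], g)
        holders = [grp for grp in combined if "x" in grp.protein_ids]
        assert len(holders) == 2
        assert all("x" in grp.ambiguous for grp in holders)

    def test_missing_bait_raises(self, make_graph):
        g = make_graph({"a": "A"}, [])
        with pytest.raises(KeyError, match="ghost"):
            combine([], [], ["ghost"], g)

    def test_never_drops_bait_cogrouped_member(self, make_graph):
        # invariant: every member placed with a bait by either algorithm
        # survives in some combined group
        g = make_graph(
            {"bait": "A", "x": "B", "y": "B", "z": "C"},
            [("bait", "x", 3.0), ("bait", "y", 2.0), ("bait", "z", 1.0)],
        )
        mcl_set = [og_("m1", [("bait", "A"), ("x", "B"), ("z", "C")], "mcl")]
        par_set = [og_("p1", [("bait", "A"), ("y", "B")], "paranoid")]
        combined = combine(mcl_set, par_set, ["bait"], g)
        placed = set().union(*(grp.protein_ids for grp in combined))
        assert {"x", "y", "z"} <= placed


# -- end-to-end recovery on synthetic proteomes ------------------------------

class TestSyntheticRecovery:
    def build(self, cfg):
        proteomes = simulate_proteomes(cfg)
        hits = simulate_similarity(proteomes)
        kept, _ = qc_filter(proteomes.all_records)
        species_of = {r.id: r.species for r in kept}
        graph = build_graph(hits, species_of)
        return proteomes, normalize_weights(graph)

    def truth_ari(self, proteomes, groups):
        truth = proteomes.truth_labels()
        labels = group_labels(groups)
        common = [p for p in truth.index if p in labels]
        assert len(common) == len(truth)  # everyone clustered
        return adjusted_rand_score(
            [truth[p] for p in common], [labels[p] for p in common]
        )

    def test_zero_mutation_limit_exact(self):
        cfg = SimulationConfig(seed=11, n_species=3, n_families=8,
                               duplication_prob=0.0, substitution_prob=0.0)
        proteomes, graph = self.build(cfg)
        assert self.truth_ari(proteomes, mcl(graph)) == 1.0
        assert self.truth_ari(proteomes, infer_paranoid(graph)) == 1.0

    def test_default_regime_combined_ari(self):
        cfg = SimulationConfig(seed=5)
        proteomes, graph = self.build(cfg)
        mcl_groups = mcl(graph)
        par_groups = infer_paranoid(graph)
        first = sorted(proteomes.records)[0]
        baits = [f"{first}_{fam}_c0"
                 for fam in sorted(proteomes.truth["family"].unique())]
        combined = combine(mcl_groups, par_groups, baits, graph)
        truth = proteomes.truth_labels()
        labels = group_labels(combined)
        common = [p for p in truth.index if p in labels]
        ari = adjusted_rand_score(
            [truth[p] for p in common], [labels[p] for p in common]
        )
        assert ari >= 0.95
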