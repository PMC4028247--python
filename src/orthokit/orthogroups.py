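"""Orthologous-group inference by two algorithms, and their combination.

Two routes are implemented over the same similarity graph:

* a Markov-clustering route: species-pair-normalized weights, column
  stochastic flow matrix, alternating expansion/inflation until the flow
  stabilizes;
* a seed/expansion route: reciprocal-best-hit seed pairs between every
  species pair, in-paralog expansion within each species, then transitive
  merging of the pairwise groups.

``combine`` unions the two results around each curated bait protein, which
trades false negatives for manual curation downstream.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .core_io_qc import EVALUE_FLOOR, SimilarityHit

#: Weight cap corresponding to the e-value floor: -log10(1e-180).
MAX_WEIGHT = 180.0


@dataclass(frozen=True)
class SeedPair:
    """A reciprocal best hit between two species, used to seed a group."""

    a: str
    b: str
    species_a: str
    species_b: str
    seed_weight: float


@dataclass(frozen=True)
class MclParams:
    inflation: float = 1.5
    evalue_cutoff: float = 1e-5
    prune_threshold: float = 1e-5
    tolerance: float = 1e-6
    max_iterations: int = 100

    def __post_init__(self) -> None:
        if self.inflation <= 1:
            raise ValueError("inflation must be > 1")
        if self.evalue_cutoff <= 0 or self.prune_threshold <= 0:
            raise ValueError("cutoffs must be positive")


@dataclass
class OrthoGroup:
    """A set of (protein id, species) members from one inference source."""

    group_id: str
    members: frozenset[tuple[str, str]]
    source: str  # mcl | paranoid | combined
    baits: frozenset[str] = field(default_factory=frozenset)
    ambiguous: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("orthogroup members must be non-empty")

    @property
    def protein_ids(self) -> frozenset[str]:
        return frozenset(p for p, _ in self.members)

    @property
    def species(self) -> frozenset[str]:
        return frozenset(s for _, s in self.members)


class SimilarityGraph:
    """Undirected similarity graph with w = -log10(evalue), capped at 180.

    Nodes are protein ids carrying a ``species`` attribute; edges carry
    ``weight`` and ``category`` (``inter`` or ``intra``).  Backed by
    :class:`networkx.Graph`.
    """

    def __init__(self, graph: nx.Graph):
        self._g = graph

    @property
    def nx(self) -> nx.Graph:
        return self._g

    def species_of(self, protein: str) -> str:
        return self._g.nodes[protein]["species"]

    def proteins(self) -> list[str]:
        return sorted(self._g.nodes)

    def weight(self, a: str, b: str) -> float:
        """Edge weight between two proteins, 0.0 if absent."""
        data = self._g.get_edge_data(a, b)
        return 0.0 if data is None else data["weight"]

    def copy(self) -> "SimilarityGraph":
        return SimilarityGraph(self._g.copy())


def evalue_to_weight(evalue: float) -> float:
    return -math.log10(max(evalue, EVALUE_FLOOR))


def build_graph(
    hits: Iterable[SimilarityHit],
    species_of: Mapping[str, str],
    cutoff: float = 1e-5,
) -> SimilarityGraph:
    """Build the undirected similarity graph from pairwise hits.

    Hits with ``evalue > cutoff`` are excluded.  When both directions of a
    pair survive, their weights are averaged into one undirected edge (MCL
    requires a symmetric matrix).  Multiple hits in the same direction keep
    the best (lowest e-value).  Self-hits are dropped.  A hit referencing a
    protein absent from ``species_of`` raises ``KeyError``.
    """
    g = nx.Graph()
    for protein in species_of:
        g.add_node(protein, species=species_of[protein])
    directed: dict[tuple[str, str], float] = {}
    for hit in hits:
        if hit.query not in species_of:
            raise KeyError(f"hit references unknown protein {hit.query!r}")
        if hit.subject not in species_of:
            raise KeyError(f"hit references unknown protein {hit.subject!r}")
        if hit.is_self or hit.evalue > cutoff:
            continue
        w = evalue_to_weight(hit.evalue)
        key = (hit.query, hit.subject)
        if w > directed.get(key, -1.0):
            directed[key] = w
    seen: set[tuple[str, str]] = set()
    for (q, s) in directed:
        pair = (q, s) if q < s else (s, q)
        if pair in seen:
            continue
        seen.add(pair)
        fwd = directed.get(pair)
        rev = directed.get((pair[1], pair[0]))
        weights = [x for x in (fwd, rev) if x is not None]
        weight = sum(weights) / len(weights)
        cat = "intra" if species_of[pair[0]] == species_of[pair[1]] else "inter"
        g.add_edge(pair[0], pair[1], weight=weight, category=cat)
    return SimilarityGraph(g)


def normalize_weights(graph: SimilarityGraph) -> SimilarityGraph:
    """Divide each edge weight by its (species-pair, category) stratum mean.

    Intra-species edges of species X form one stratum; inter-species edges
    of each unordered pair (X, Y) form another.  Single-edge strata come out
    at exactly 1.0.
    """
    out = graph.copy()
    g = out.nx
    strata: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for u, v in g.edges:
        su, sv = g.nodes[u]["species"], g.nodes[v]["species"]
        key = tuple(sorted((su, sv)))
        strata.setdefault(key, []).append((u, v))
    for edges in strata.values():
        mean = sum(g.edges[e]["weight"] for e in edges) / len(edges)
        if mean == 0:
            continue
        for e in edges:
            g.edges[e]["weight"] /= mean
    return out


def _stochastic(m: np.ndarray) -> np.ndarray:
    sums = m.sum(axis=0)
    sums[sums == 0] = 1.0
    return m / sums


def mcl(
    graph: SimilarityGraph, params: MclParams | None = None
) -> list[OrthoGroup]:
    """Markov clustering of the (normalized) similarity graph.

    Self-loops are added with weight equal to the node's maximum incident
    weight (1.0 for isolated nodes), the matrix is made column stochastic,
    and expansion (matrix squaring) alternates with inflation (elementwise
    power ``params.inflation``, column renormalization, pruning of entries
    below ``params.prune_threshold``) until the largest entry change drops
    below ``params.tolerance``.  Clusters are the connected components of
    the non-zero support of the attractor matrix.  Deterministic: nodes are
    processed in sorted order.
    """
    params = params or MclParams()
    nodes = graph.proteins()
    n = len(nodes)
    if n == 0:
        return []
    index = {p: i for i, p in enumerate(nodes)}
    m = np.zeros((n, n))
    for u, v, data in graph.nx.edges(data=True):
        m[index[u], index[v]] = data["weight"]
        m[index[v], index[u]] = data["weight"]
    loops = m.max(axis=0)
    loops[loops == 0] = 1.0
    m[np.diag_indices(n)] = loops
    m = _stochastic(m)
    converged = False
    for _ in range(params.max_iterations):
        prev = m
        m = m @ m
        m = np.power(m, params.inflation)
        m = _stochastic(m)
        m[m < params.prune_threshold] = 0.0
        m = _stochastic(m)
        if np.abs(m - prev).max() < params.tolerance:
            converged = True
            break
    if not converged:
        warnings.warn("MCL did not converge within max_iterations", RuntimeWarning)
    support = nx.Graph()
    support.add_nodes_from(range(n))
    rows, cols = np.nonzero(m)
    support.add_edges_from(zip(rows.tolist(), cols.tolist()))
    groups = []
    comps = sorted(nx.connected_components(support), key=lambda c: nodes[min(c)])
    for i, comp in enumerate(comps, start=1):
        members = frozenset(
            (nodes[j], graph.species_of(nodes[j])) for j in comp
        )
        groups.append(OrthoGroup(group_id=f"mcl_{i:04d}", members=members, source="mcl"))
    return groups


def reciprocal_best_hits(
    graph: SimilarityGraph, species_a: str, species_b: str
) -> list[SeedPair]:
    """Reciprocal best hits between two species over inter-species edges.

    (a, b) is returned iff b is a's highest-weight partner in species B and
    a is b's highest-weight partner in species A.  Weight ties break toward
    the lexicographically smaller partner id.
    """
    if species_a == species_b:
        raise ValueError("species must differ for an RBH search")
    g = graph.nx
    members_a = sorted(n for n in g if g.nodes[n]["species"] == species_a)
    members_b = {n for n in g if g.nodes[n]["species"] == species_b}

    def best_partner(node: str, pool: set[str] | list[str]) -> str | None:
        candidates = [
            (-(g.edges[node, nb]["weight"]), nb)
            for nb in g[node]
            if nb in pool
        ]
        if not candidates:
            return None
        return min(candidates)[1]

    pool_a = set(members_a)
    pairs = []
    for a in members_a:
        b = best_partner(a, members_b)
        if b is None:
            continue
        if best_partner(b, pool_a) == a:
            pairs.append(
                SeedPair(
                    a=a,
                    b=b,
                    species_a=species_a,
                    species_b=species_b,
                    seed_weight=g.edges[a, b]["weight"],
                )
            )
    return pairs


def expand_in_paralogs(seed: SeedPair, graph: SimilarityGraph) -> OrthoGroup:
    """Grow a pairwise group from a seed pair by in-paralog inclusion.

    A same-species protein joins when its intra-species weight to the seed
    member is >= the seed weight.
    """
    g = graph.nx
    members = {(seed.a, seed.species_a), (seed.b, seed.species_b)}
    for anchor, species in ((seed.a, seed.species_a), (seed.b, seed.species_b)):
        for nb in g[anchor]:
            if g.nodes[nb]["species"] != species:
                continue
            if g.edges[anchor, nb]["weight"] >= seed.seed_weight:
                members.add((nb, species))
    return OrthoGroup(
        group_id=f"seed_{seed.a}_{seed.b}",
        members=frozenset(members),
        source="paranoid",
    )


def merge_pairwise_groups(groups: Sequence[OrthoGroup]) -> list[OrthoGroup]:
    """Transitively merge pairwise groups sharing any member (union-find)."""
    overlap = nx.Graph()
    for i, grp in enumerate(groups):
        overlap.add_node(i)
        for member in grp.members:
            overlap.add_edge(i, member)
    merged: list[OrthoGroup] = []
    comps = []
    for comp in nx.connected_components(overlap):
        members = frozenset(m for m in comp if isinstance(m, tuple))
        if members:
            comps.append(members)
    comps.sort(key=lambda ms: min(ms))
    for i, members in enumerate(comps, start=1):
        merged.append(
            OrthoGroup(group_id=f"par_{i:04d}", members=members, source="paranoid")
        )
    return merged


def infer_paranoid(graph: SimilarityGraph) -> list[OrthoGroup]:
    """Full seed/expansion route over every species pair."""
    species = sorted({graph.species_of(p) for p in graph.proteins()})
    pairwise: list[OrthoGroup] = []
    for sp_a, sp_b in combinations(species, 2):
        for seed in reciprocal_best_hits(graph, sp_a, sp_b):
            pairwise.append(expand_in_paralogs(seed, graph))
    return merge_pairwise_groups(pairwise)


def combine(
    mcl_set: Sequence[OrthoGroup],
    paranoid_set: Sequence[OrthoGroup],
    baits: Iterable[str],
    graph: SimilarityGraph,
) -> list[OrthoGroup]:
    """Union the two groupings around each bait protein.

    For every bait, the combined group is the union of all members either
    algorithm co-grouped with it (union keeps false negatives down at the
    cost of false positives).  Bait groups sharing a bait member merge.  A
    non-bait protein claimed by two different bait groups goes to the one
    whose bait it is most similar to; an exact weight tie keeps it in both,
    flagged ambiguous.  Proteins co-grouped with no bait are left out.
    """
    bait_list = sorted(set(baits))
    universe = set(graph.proteins())
    for bait in bait_list:
        if bait not in universe:
            raise KeyError(f"bait {bait!r} absent from the protein universe")
    bait_set = set(bait_list)

    co_members: dict[str, set[tuple[str, str]]] = {b: set() for b in bait_list}
    for grp in list(mcl_set) + list(paranoid_set):
        ids = grp.protein_ids
        present = ids & bait_set
        for bait in present:
            co_members[bait] |= set(grp.members)
    for bait in bait_list:
        co_members[bait].add((bait, graph.species_of(bait)))

    # merge bait clusters transitively when one bait falls in another's set
    bait_graph = nx.Graph()
    bait_graph.add_nodes_from(bait_list)
    for bait in bait_list:
        for other in {p for p, _ in co_members[bait]} & bait_set:
            if other != bait:
                bait_graph.add_edge(bait, other)
    clusters = sorted(nx.connected_components(bait_graph), key=min)

    cluster_members: list[set[tuple[str, str]]] = []
    for cluster in clusters:
        members: set[tuple[str, str]] = set()
        for bait in cluster:
            members |= co_members[bait]
        cluster_members.append(members)

    # resolve non-bait proteins claimed by several clusters
    claims: dict[str, list[int]] = {}
    for ci, members in enumerate(cluster_members):
        for pid, _ in members:
            if pid not in bait_set:
                claims.setdefault(pid, []).append(ci)
    ambiguous: dict[int, set[str]] = {}
    for pid, cluster_ids in claims.items():
        if len(cluster_ids) < 2:
            continue
        scores = []
        for ci in cluster_ids:
            best = max(graph.weight(pid, b) for b in clusters[ci])
            scores.append((best, ci))
        best_score = max(s for s, _ in scores)
        winners = [ci for s, ci in scores if s == best_score]
        if len(winners) == 1:
            for ci in cluster_ids:
                if ci != winners[0]:
                    cluster_members[ci] = {
                        m for m in cluster_members[ci] if m[0] != pid
                    }
        else:
            for ci in cluster_ids:
                if ci in winners:
                    ambiguous.setdefault(ci, set()).add(pid)
                else:
                    cluster_members[ci] = {
                        m for m in cluster_members[ci] if m[0] != pid
                    }

    out: list[OrthoGroup] = []
    for i, (cluster, members) in enumerate(zip(clusters, cluster_members), start=1):
        out.append(
            OrthoGroup(
                group_id=f"comb_{i:04d}",
                members=frozenset(members),
                source="combined",
                baits=frozenset(cluster),
                ambiguous=frozenset(ambiguous.get(i - 1, set())),
            )
        )
    return out


def write_orthogroups(groups: Iterable[OrthoGroup], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("group_id\tprotein_id\tspecies\tsource\tambiguity_flag\n")
        for grp in groups:
            for pid, sp in sorted(grp.members):
                flag = "1" if pid in grp.ambiguous else "0"
                fh.write(f"{grp.group_id}\t{pid}\t{sp}\t{grp.source}\t{flag}\n")
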