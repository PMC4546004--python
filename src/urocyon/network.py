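"""Median-joining haplotype networks, node polarity and rho dating.

The network construction follows the median-joining algorithm: build the
minimum spanning network (MSN) over the sampled haplotypes under an epsilon
relaxation, then repeatedly add quasi-median vectors (position-wise majority
consensus of connected triplets, i.e. inferred unsampled haplotypes) whose
connection cost is within epsilon of the minimum, until no new vectors
arise; finally delete obsolete median vectors. Edge weights are Hamming
mutation counts over unambiguous sites.

rho for a haplogroup is the mean shortest-path mutation count from an
ancestral node to each sampled individual, with the Saillard standard
deviation computed from the per-branch descendant flows; ties among
co-shortest paths are averaged.
"""

from __future__ import annotations

import hashlib
import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .errors import ConfigError, DataError

__all__ = [
    "HaplotypeNetwork",
    "NodeClassification",
    "RhoEstimate",
    "hamming",
    "build_mjn",
    "classify_nodes",
    "rho_estimate",
]

_SKIP = {"N", "-"}


def hamming(a: str, b: str) -> int:
    """Number of differing sites, skipping positions with N or a gap."""
    if len(a) != len(b):
        raise DataError("sequences of unequal length")
    return sum(
        1 for x, y in zip(a, b) if x != y and x not in _SKIP and y not in _SKIP
    )


def _connection_levels(seqs: list[str]) -> dict[frozenset[int], int]:
    """For every pair of node indices, the MSN level at which they connect.

    The level of a pair is the smallest d such that the two nodes are
    connected using only edges of Hamming distance <= d; an edge (u, v) is a
    feasible link at relaxation epsilon iff d(u, v) <= level(u, v) + epsilon.
    """
    n = len(seqs)
    dist = {}
    for i, j in itertools.combinations(range(n), 2):
        dist[(i, j)] = hamming(seqs[i], seqs[j])
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    levels: dict[frozenset[int], int] = {}
    unassigned = set(dist)
    for d in sorted(set(dist.values())):
        for (i, j), dij in dist.items():
            if dij == d:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
        for pair in list(unassigned):
            i, j = pair
            if find(i) == find(j):
                levels[frozenset(pair)] = d
                unassigned.discard(pair)
        if not unassigned:
            break
    return levels


def _feasible_links(seqs: list[str], epsilon: int) -> dict[frozenset[int], int]:
    """Feasible links {pair: weight} of the epsilon-relaxed MSN."""
    levels = _connection_levels(seqs)
    links = {}
    for pair, level in levels.items():
        i, j = sorted(pair)
        d = hamming(seqs[i], seqs[j])
        if d <= level + epsilon:
            links[frozenset((i, j))] = d
    return links


_MAX_TIE_POSITIONS = 6  # cap on fully-tied positions when expanding quasi-medians


def quasi_medians(a: str, b: str, c: str) -> list[str]:
    """Position-wise majority consensus of three aligned sequences.

    Where all three states differ the median is ambiguous and every choice
    is generated (the quasi-median set), capped to keep the expansion
    bounded; ambiguity codes are carried through untouched.
    """
    fixed: list[str] = []
    tied: list[tuple[int, tuple[str, str, str]]] = []
    for idx, (x, y, z) in enumerate(zip(a, b, c)):
        if x == y or x == z:
            fixed.append(x)
        elif y == z:
            fixed.append(y)
        else:
            fixed.append("")
            tied.append((idx, (x, y, z)))
    if not tied:
        return ["".join(fixed)]
    if len(tied) > _MAX_TIE_POSITIONS:
        warnings.warn(
            f"{len(tied)} fully-tied positions in a median triplet; "
            f"expanding only the first {_MAX_TIE_POSITIONS}"
        )
        for idx, states in tied[_MAX_TIE_POSITIONS:]:
            fixed[idx] = states[0]
        tied = tied[:_MAX_TIE_POSITIONS]
    out = []
    for combo in itertools.product(*(states for _, states in tied)):
        variant = list(fixed)
        for (idx, _), state in zip(tied, combo):
            variant[idx] = state
        out.append("".join(variant))
    return out


@dataclass
class HaplotypeNetwork:
    """A haplotype network: sampled haplotypes plus inferred median vectors."""

    graph: nx.Graph
    sequences: dict[str, str]
    sampled: set[str]
    multiplicities: dict[str, int]
    populations: dict[str, dict[str, int]] = field(default_factory=dict)
    epsilon: int = 0

    @property
    def median_vectors(self) -> list[str]:
        return [n for n in self.graph.nodes if n not in self.sampled]

    def is_connected(self) -> bool:
        return nx.is_connected(self.graph)

    def total_length(self) -> int:
        return int(sum(w for _, _, w in self.graph.edges.data("weight")))

    def write_edge_list(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# median-joining network edge list\n")
            fh.write("node1\tnode2\tweight\n")
            for u, v, w in sorted(self.graph.edges.data("weight")):
                fh.write(f"{u}\t{v}\t{w}\n")

    def write_graphml(self, path) -> None:
        g = nx.Graph()
        for node in self.graph.nodes:
            g.add_node(
                node,
                sampled=node in self.sampled,
                multiplicity=self.multiplicities.get(node, 0),
                sequence=self.sequences[node],
                populations=";".join(
                    f"{p}:{c}" for p, c in sorted(self.populations.get(node, {}).items())
                ),
            )
        for u, v, w in self.graph.edges.data("weight"):
            g.add_edge(u, v, weight=int(w))
        nx.write_graphml(g, str(path))


def _sampled_pair_distances(
    seqs: list[str], links: Mapping[frozenset[int], int], sampled_idx: list[int]
) -> dict[frozenset[int], float]:
    g = nx.Graph()
    g.add_nodes_from(range(len(seqs)))
    for pair, w in links.items():
        i, j = sorted(pair)
        g.add_edge(i, j, weight=w)
    out = {}
    lengths = dict(nx.all_pairs_dijkstra_path_length(g, weight="weight"))
    for i, j in itertools.combinations(sampled_idx, 2):
        out[frozenset((i, j))] = lengths[i].get(j, np.inf)
    return out


def build_mjn(
    sequences: Mapping[str, str] | Sequence[tuple[str, str]],
    multiplicities: Mapping[str, int] | None = None,
    populations: Mapping[str, Mapping[str, int]] | None = None,
    epsilon: int = 0,
    max_iterations: int = 50,
) -> HaplotypeNetwork:
    """Construct a median-joining network from named haplotype sequences.

    Duplicate sequences under distinct names are merged (multiplicities
    summed) with a warning. epsilon is the relaxation parameter of the
    feasible-link and median-cost criteria; 0 is the published default.
    """
    if epsilon < 0:
        raise ConfigError("epsilon must be >= 0")
    items = list(sequences.items()) if isinstance(sequences, Mapping) else list(sequences)
    if not items:
        raise DataError("no haplotypes")
    lengths = {len(s) for _, s in items}
    if len(lengths) != 1:
        raise DataError(f"sequences of unequal length: {sorted(lengths)}")
    multiplicities = dict(multiplicities or {n: 1 for n, _ in items})
    populations = {n: dict(p) for n, p in (populations or {}).items()}

    # merge duplicate sequences
    by_seq: dict[str, str] = {}
    names: list[str] = []
    seqs: list[str] = []
    mult: dict[str, int] = {}
    pops: dict[str, dict[str, int]] = {}
    for name, seq in items:
        if seq in by_seq:
            keep = by_seq[seq]
            warnings.warn(f"haplotypes {keep} and {name} are identical; merged")
            mult[keep] += multiplicities.get(name, 1)
            for p, c in populations.get(name, {}).items():
                pops.setdefault(keep, {})[p] = pops.get(keep, {}).get(p, 0) + c
            continue
        by_seq[seq] = name
        names.append(name)
        seqs.append(seq)
        mult[name] = multiplicities.get(name, 1)
        if name in populations:
            pops[name] = populations[name]

    n_sampled = len(seqs)
    sampled_idx = list(range(n_sampled))
    mv_names: dict[int, str] = {}
    max_nodes = 20 * n_sampled + 50

    for _ in range(max_iterations):
        links = _feasible_links(seqs, epsilon)
        # every feasible link (u, v) combined with each third node forms a
        # candidate triplet for quasi-median generation
        triples: set[tuple[int, int, int]] = set()
        for pair in links:
            i, j = sorted(pair)
            for w in range(len(seqs)):
                if w != i and w != j:
                    triples.add(tuple(sorted((i, j, w))))
        candidates: dict[str, int] = {}
        existing = set(seqs)
        for u, v, w in triples:
            for m in quasi_medians(seqs[u], seqs[v], seqs[w]):
                if m in existing:
                    continue
                cost = (
                    hamming(seqs[u], m) + hamming(seqs[v], m) + hamming(seqs[w], m)
                )
                if m not in candidates or cost < candidates[m]:
                    candidates[m] = cost
        if not candidates:
            break
        lam = min(candidates.values())
        new = [m for m, c in candidates.items() if c <= lam + epsilon]
        if len(seqs) + len(new) > max_nodes:
            warnings.warn("median-vector budget exhausted; stopping early")
            break
        for m in sorted(new):  # sorted for deterministic naming
            idx = len(seqs)
            digest = hashlib.sha1(m.encode()).hexdigest()[:8]
            mv_names[idx] = f"mv{len(mv_names) + 1}_{digest}"
            seqs.append(m)
    else:
        warnings.warn("median-joining did not converge within max_iterations")

    # a sampled-MSN link is kept unless the medians supersede it with an
    # equally short path, so no sampled pair is ever stretched beyond its
    # MSN connection while superseded links (and the cycles they would
    # close) are dropped
    sampled_links = _feasible_links(seqs[:n_sampled], epsilon)

    def _links_with_msn(node_seqs: list[str]) -> dict[frozenset[int], int]:
        merged = _feasible_links(node_seqs, epsilon)
        g = nx.Graph()
        g.add_nodes_from(range(len(node_seqs)))
        for pair, w in merged.items():
            i, j = sorted(pair)
            g.add_edge(i, j, weight=w)
        for pair in sorted(sampled_links, key=lambda p: (sampled_links[p], sorted(p))):
            if pair in merged:
                continue
            i, j = sorted(pair)
            w = sampled_links[pair]
            try:
                current = nx.shortest_path_length(g, i, j, weight="weight")
            except nx.NetworkXNoPath:
                current = np.inf
            if current > w:
                g.add_edge(i, j, weight=w)
                merged[pair] = w
        return merged

    # delete obsolete median vectors: unsampled, degree <= 2, and removable
    # without stretching any sampled-to-sampled shortest connection
    links = _links_with_msn(seqs)
    baseline = _sampled_pair_distances(seqs, links, sampled_idx)
    removed = True
    while removed:
        removed = False
        degree: dict[int, int] = {i: 0 for i in range(len(seqs))}
        for pair in links:
            for i in pair:
                degree[i] += 1
        for idx in range(n_sampled, len(seqs)):
            if idx >= len(seqs) or degree.get(idx, 0) > 2:
                continue
            trial_seqs = seqs[:idx] + seqs[idx + 1 :]
            trial_links = _links_with_msn(trial_seqs)
            trial_dist = _sampled_pair_distances(
                trial_seqs, trial_links, sampled_idx
            )
            if all(
                trial_dist[pair] <= baseline[pair] for pair in baseline
            ):
                seqs = trial_seqs
                mv_names = {
                    (k if k < idx else k - 1): v
                    for k, v in mv_names.items()
                    if k != idx
                }
                links = trial_links
                removed = True
                break

    node_names = {
        i: (names[i] if i < n_sampled else mv_names[i]) for i in range(len(seqs))
    }
    graph = nx.Graph()
    for i, name in node_names.items():
        graph.add_node(name)
    for pair, w in links.items():
        i, j = sorted(pair)
        graph.add_edge(node_names[i], node_names[j], weight=int(w))
    return HaplotypeNetwork(
        graph=graph,
        sequences={node_names[i]: seqs[i] for i in node_names},
        sampled=set(names),
        multiplicities=mult,
        populations=pops,
        epsilon=epsilon,
    )


@dataclass(frozen=True)
class NodeClassification:
    """Tip/interior labels and the root-proximal node."""

    tips: tuple[str, ...]
    interior: tuple[str, ...]
    root_proximal: str | None = None
    root_ties: tuple[str, ...] = ()


def classify_nodes(
    network: HaplotypeNetwork,
    root_hint: Iterable[str] | str | None = None,
) -> NodeClassification:
    """Label sampled nodes as tips (degree 1) or interior; find the root side.

    ``root_hint`` is either a designated node name or a collection of
    outgroup sequences; the sampled node closest (minimum Hamming distance)
    to any hint sequence is flagged root-proximal, ties broken by lowest
    name with all ties reported.
    """
    if not network.is_connected():
        raise DataError("network is not connected")
    tips = tuple(
        sorted(
            n
            for n in network.sampled
            if n in network.graph and network.graph.degree(n) == 1
        )
    )
    interior = tuple(sorted(set(network.graph.nodes) - set(tips)))
    root, ties = None, ()
    if root_hint is not None:
        if isinstance(root_hint, str) and root_hint in network.graph:
            root = root_hint
        else:
            hints = [root_hint] if isinstance(root_hint, str) else list(root_hint)
            best: dict[str, int] = {}
            for node in sorted(network.sampled):
                best[node] = min(
                    hamming(network.sequences[node], h) for h in hints
                )
            lo = min(best.values())
            tied = tuple(sorted(n for n, d in best.items() if d == lo))
            root = tied[0]
            ties = tied
            if len(tied) > 1:
                warnings.warn(
                    f"root hint equidistant from {len(tied)} nodes: {tied}; "
                    f"choosing {root}"
                )
    return NodeClassification(
        tips=tips, interior=interior, root_proximal=root, root_ties=ties
    )


@dataclass(frozen=True)
class RhoEstimate:
    """rho and its Saillard SD for one ancestor/descendant-set pair."""

    ancestor: str
    descendants: tuple[str, ...]
    rho: float
    sd: float
    n: int

    def to_time(self, rates):
        """Convert to a TimeEstimate with a dating RateModel."""
        from .dating import rho_to_time

        return rho_to_time(self.rho, self.sd, rates)


def rho_estimate(
    network: HaplotypeNetwork,
    ancestor: str,
    descendants: Mapping[str, int] | Sequence[str] | None = None,
) -> RhoEstimate:
    """rho = frequency-weighted mean mutation count ancestor -> individuals.

    Descendants may carry explicit multiplicities; by default the network's
    sampled multiplicities are used for all sampled haplotypes. When a
    haplotype has several co-shortest paths to the ancestor its weight is
    split equally among them (this only affects the SD: all co-shortest
    paths share one length).
    """
    if ancestor not in network.graph:
        raise DataError(f"ancestor {ancestor!r} not in network")
    if descendants is None:
        descendants = {n: network.multiplicities.get(n, 1) for n in network.sampled}
    elif not isinstance(descendants, Mapping):
        descendants = {n: network.multiplicities.get(n, 1) for n in descendants}
    if not descendants:
        raise DataError("empty descendant set")
    for node in descendants:
        if node not in network.graph:
            raise DataError(f"descendant {node!r} not in network")
        if not nx.has_path(network.graph, ancestor, node):
            raise DataError(f"{node!r} not connected to ancestor")

    n = sum(descendants.values())
    total = 0.0
    flows: dict[tuple[str, str], float] = {}
    ambiguous = False
    for node, m in descendants.items():
        if node == ancestor:
            continue
        length = nx.shortest_path_length(
            network.graph, ancestor, node, weight="weight"
        )
        total += m * length
        paths = list(
            nx.all_shortest_paths(network.graph, ancestor, node, weight="weight")
        )
        if len(paths) > 1:
            ambiguous = True
        share = m / len(paths)
        for path in paths:
            for u, v in zip(path, path[1:]):
                key = (u, v) if u < v else (v, u)
                flows[key] = flows.get(key, 0.0) + share
    if ambiguous:
        warnings.warn(
            "co-shortest paths to the ancestor; branch flows averaged over them"
        )
    rho = total / n
    var = sum(
        (flow / n) ** 2 * network.graph.edges[u, v]["weight"]
        for (u, v), flow in flows.items()
    )
    return RhoEstimate(
        ancestor=ancestor,
        descendants=tuple(sorted(descendants)),
        rho=rho,
        sd=float(np.sqrt(var)),
        n=int(n),
    )
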