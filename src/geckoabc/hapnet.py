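"""Haplotype collapsing and median-joining networks.

The median-joining construction follows the Bandelt-Forster-Roehl scheme:
iterate between (a) building an epsilon-relaxed minimum spanning network
(MSN) over the current node set and (b) adding quasi-median vectors of MSN
triplets whenever they reduce the total network cost, defined here as the
weight of a minimum spanning tree over the node set in Hamming space.
Unsampled nodes of degree <= 2 are pruned at the end. All characters carry
weight 1 and states are restricted to {A, C, G, T}: sites holding gaps or
ambiguity codes in any sequence are removed before collapsing (complete
deletion), which keeps the construction deterministic.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .iodata import SequenceAlignment

logger = logging.getLogger(__name__)


@dataclass
class HaplotypeTable:
    """Collapsed haplotypes with per-population frequencies.

    ``sequences`` maps haplotype ID (H1, H2, ... in order of first
    appearance) to the retained-site sequence; ``frequencies`` holds total
    counts and ``pop_frequencies`` per-population counts; ``member_of`` maps
    each input sequence ID to its haplotype.
    """

    sequences: dict[str, str]
    frequencies: dict[str, int]
    pop_frequencies: dict[str, dict[str, int]]
    member_of: dict[str, str]
    retained_sites: list[int]

    @property
    def n_haplotypes(self) -> int:
        return len(self.sequences)

    @property
    def n_sequences(self) -> int:
        return sum(self.frequencies.values())

    def private_haplotypes(self, population: str) -> list[str]:
        """Haplotypes observed in ``population`` and nowhere else."""
        out = []
        for hap, freqs in self.pop_frequencies.items():
            present = [p for p, c in freqs.items() if c > 0]
            if present == [population]:
                out.append(hap)
        return out

    def expand_pool(self) -> list[str]:
        """Haplotype label per input sequence (the rarefaction sampling pool)."""
        return [self.member_of[sid] for sid in self.member_of]


def collapse_haplotypes(aln: SequenceAlignment, site_policy: str = "complete") -> HaplotypeTable:
    """Collapse an alignment into distinct haplotypes on retained sites.

    ``site_policy='complete'`` drops every column containing N or '-' in any
    sequence before comparing; ``'none'`` keeps all columns and treats N/'-'
    as ordinary states. Raises if no site survives.
    """
    if aln.n == 0:
        raise ValueError("empty alignment")
    arr = aln.to_array()
    if site_policy == "complete":
        valid = ((arr == b"A") | (arr == b"C") | (arr == b"G") | (arr == b"T")).all(axis=0)
        retained = np.flatnonzero(valid).tolist()
    elif site_policy == "none":
        retained = list(range(aln.length))
    else:
        raise ValueError(f"unknown site_policy {site_policy!r}")
    if not retained and aln.length > 0:
        raise ValueError("all alignment sites dropped by the site policy")
    seqs = ["".join(s[j] for j in retained) for s in aln.sequences]
    hap_ids: dict[str, str] = {}
    sequences: dict[str, str] = {}
    frequencies: dict[str, int] = {}
    pop_frequencies: dict[str, dict[str, int]] = {}
    member_of: dict[str, str] = {}
    for sid, pop, s in zip(aln.ids, aln.populations, seqs):
        if s not in hap_ids:
            hid = f"H{len(hap_ids) + 1}"
            hap_ids[s] = hid
            sequences[hid] = s
            frequencies[hid] = 0
            pop_frequencies[hid] = {}
        hid = hap_ids[s]
        frequencies[hid] += 1
        pop_frequencies[hid][pop] = pop_frequencies[hid].get(pop, 0) + 1
        member_of[sid] = hid
    return HaplotypeTable(sequences, frequencies, pop_frequencies, member_of, retained)


# ---------------------------------------------------------------------------
# median joining


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _distance_matrix(seqs: list[str]) -> np.ndarray:
    arr = np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(len(seqs), -1)
    return (arr[:, None, :] != arr[None, :, :]).sum(axis=2)


def _msn_edges(seqs: list[str], epsilon: int) -> list[tuple[int, int, int]]:
    """Edges of the epsilon-relaxed minimum spanning network.

    Distances are processed in ascending order; an edge joining two groups is
    kept whenever its weight is within epsilon of the smallest weight at
    which those groups become connectable (Bandelt's MSN generalisation).
    """
    n = len(seqs)
    if n == 1:
        return []
    d = _distance_matrix(seqs)
    pairs = [(int(d[i, j]), i, j) for i in range(n) for j in range(i + 1, n)]
    pairs.sort()
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edges: list[tuple[int, int, int]] = []
    distances = sorted({w for w, _, _ in pairs})
    # connection level between component pairs is discovered distance by distance
    for w in distances:
        batch = [(wi, i, j) for wi, i, j in pairs if w <= wi <= w + epsilon]
        # keep edges whose endpoints are in components not yet connected at w
        newly = [(wi, i, j) for wi, i, j in batch if find(i) != find(j)]
        for wi, i, j in newly:
            edges.append((i, j, wi))
        for wi, i, j in newly:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj
        if all(find(i) == find(0) for i in range(n)):
            # still allow ties/epsilon at this final level, then stop
            break
    return edges


def _mst_cost(seqs: list[str]) -> int:
    """Minimum spanning tree weight of the complete Hamming graph (Prim)."""
    n = len(seqs)
    if n <= 1:
        return 0
    d = _distance_matrix(seqs)
    in_tree = np.zeros(n, dtype=bool)
    in_tree[0] = True
    best = d[0].astype(float)
    best[0] = np.inf
    cost = 0
    for _ in range(n - 1):
        j = int(np.argmin(best))
        cost += int(best[j])
        in_tree[j] = True
        best = np.minimum(best, d[j])
        best[in_tree] = np.inf
    return cost


def _quasi_medians(a: str, b: str, c: str) -> list[str]:
    """Quasi-median set of three sequences: per-site majority; a site where
    all three states differ contributes each of the three options."""
    options = []
    for x, y, z in zip(a, b, c):
        if x == y or x == z:
            options.append((x,))
        elif y == z:
            options.append((y,))
        else:
            options.append((x, y, z))
    total = 1
    for o in options:
        total *= len(o)
        if total > 729:  # 3^6 safety bound; degenerate triples only
            logger.warning("quasi-median set truncated for a highly divergent triple")
            return []
    return ["".join(t) for t in itertools.product(*options)]


def median_joining(ht: HaplotypeTable, epsilon: int = 0) -> nx.Graph:
    """Median-joining network of a haplotype table.

    Returns a networkx graph whose nodes are haplotype IDs (sampled) and
    ``MV1``, ``MV2``, ... (median vectors); nodes carry ``kind``,
    ``sequence`` and ``frequencies`` attributes and edges an integer
    ``mutations`` count. When several candidate medians yield the same cost
    reduction the lexicographically smallest sequence is added first, making
    the output deterministic.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be a non-negative integer")
    sampled = list(ht.sequences.values())
    if len(set(sampled)) != len(sampled):
        raise ValueError("haplotype table contains duplicate sequences")
    nodes = list(sampled)
    # --- median addition loop
    while True:
        cost = _mst_cost(nodes)
        edges = _msn_edges(nodes, epsilon)
        adj: dict[int, set[int]] = {i: set() for i in range(len(nodes))}
        for i, j, _ in edges:
            adj[i].add(j)
            adj[j].add(i)
        candidates: set[str] = set()
        for u in adj:
            neigh = sorted(adj[u])
            for v, w in itertools.combinations(neigh, 2):
                for m in _quasi_medians(nodes[u], nodes[v], nodes[w]):
                    if m not in nodes:
                        candidates.add(m)
        best_seq = None
        best_cost = cost
        for m in sorted(candidates):  # lexicographic order fixes tie-breaking
            c = _mst_cost(nodes + [m])
            if c < best_cost:
                best_cost = c
                best_seq = m
        if best_seq is None:
            break
        nodes.append(best_seq)
    # --- prune unsampled nodes of degree <= 2 (iterate to closure)
    sampled_set = set(sampled)
    while True:
        edges = _msn_edges(nodes, epsilon)
        degree = {i: 0 for i in range(len(nodes))}
        for i, j, _ in edges:
            degree[i] += 1
            degree[j] += 1
        drop = [i for i in range(len(nodes)) if nodes[i] not in sampled_set and degree[i] <= 2]
        if not drop:
            break
        nodes = [s for i, s in enumerate(nodes) if i not in set(drop)]
    # --- assemble final graph
    seq_to_hid = {s: h for h, s in ht.sequences.items()}
    names = []
    mv = 0
    for s in nodes:
        if s in seq_to_hid:
            names.append(seq_to_hid[s])
        else:
            mv += 1
            names.append(f"MV{mv}")
    g = nx.Graph(epsilon=epsilon)
    for name, s in zip(names, nodes):
        kind = "sampled" if s in seq_to_hid else "median"
        freqs = ht.pop_frequencies.get(name, {}) if kind == "sampled" else {}
        g.add_node(name, kind=kind, sequence=s, frequencies=dict(freqs))
    for i, j, w in _msn_edges(nodes, epsilon):
        g.add_edge(names[i], names[j], mutations=int(w))
    return g


def network_cost(net: nx.Graph) -> int:
    """MST weight over the final node set (total mutation cost of the network)."""
    seqs = [d["sequence"] for _, d in net.nodes(data=True)]
    return _mst_cost(seqs)
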