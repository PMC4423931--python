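"""Permutation test for direct PPI connectivity among deleted genes.

Genes overlapped by a cohort's deletions ("seed genes") are tested for an
excess of direct protein-protein interactions among themselves. The null
model relabels seed status among network nodes *within degree bins*, so each
permuted seed set has (approximately) the degree profile of the observed
one — high-degree hubs cannot inflate the statistic. The p-value uses the
add-one estimator p = (1 + #{permutation >= observed}) / (n_perm + 1), which
is never zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import FormatError

log = logging.getLogger(__name__)


@dataclass
class PpiGraph:
    """An undirected PPI network: deduplicated edges, no self-loops."""

    nodes: list[str]
    edges: np.ndarray  # (m, 2) int32 indices into nodes
    node_index: dict[str, int] = field(repr=False, default_factory=dict)

    def __post_init__(self):
        if not self.node_index:
            self.node_index = {n: i for i, n in enumerate(self.nodes)}

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        np.add.at(deg, self.edges.ravel(), 1)
        return deg

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from((self.nodes[u], self.nodes[v]) for u, v in self.edges)
        return g

    @classmethod
    def from_edges(cls, pairs: Sequence[tuple[str, str]]) -> "PpiGraph":
        nodes = sorted({g for pair in pairs for g in pair})
        index = {n: i for i, n in enumerate(nodes)}
        seen: set[tuple[int, int]] = set()
        n_self = 0
        for a, b in pairs:
            if a == b:
                n_self += 1
                continue
            u, v = index[a], index[b]
            seen.add((min(u, v), max(u, v)))
        if n_self:
            log.info("dropped %d self-loop(s)", n_self)
        edges = np.array(sorted(seen), dtype=np.int32).reshape(-1, 2)
        return cls(nodes=nodes, edges=edges, node_index=index)


def build_ppi(edge_list_path) -> PpiGraph:
    """Read a two-column TSV of gene symbols into a deduplicated graph.

    A header line is tolerated (detected by common column-name words);
    fewer than two columns on any line is a format error; an empty file is
    an error.
    """
    pairs: list[tuple[str, str]] = []
    with open(edge_list_path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            s = raw.strip()
            if not s or s.startswith("#"):
                continue
            fields = s.split("\t")
            if len(fields) < 2:
                raise FormatError(
                    f"{edge_list_path} line {lineno}: expected two tab-separated columns"
                )
            if lineno == 1 and fields[0].lower() in ("gene_a", "gene1", "protein_a", "source"):
                continue
            pairs.append((fields[0], fields[1]))
    if not pairs:
        raise FormatError(f"{edge_list_path}: no edges found")
    return PpiGraph.from_edges(pairs)


@dataclass
class ConnectivityResult:
    seed_genes: frozenset[str]
    direct_edge_count: int
    p_network: float
    per_gene_p: dict[str, float]
    n_perm: int
    dropped_seeds: frozenset[str] = frozenset()


def _degree_bins(degrees: np.ndarray, min_bin_size: int) -> list[np.ndarray]:
    """Partition node indices into bins of equal degree, pooling small bins.

    Nodes are grouped by degree; adjacent degree groups are pooled until
    each bin holds at least ``min_bin_size`` nodes (the final bin absorbs
    any remainder).
    """
    order = np.argsort(degrees, kind="stable")
    sorted_deg = degrees[order]
    bins: list[np.ndarray] = []
    start = 0
    n = len(order)
    while start < n:
        end = start + 1
        # include the full run of equal degrees, then extend until bin is big enough
        while end < n and (end - start < min_bin_size or sorted_deg[end] == sorted_deg[end - 1]):
            end += 1
        bins.append(order[start:end])
        start = end
    if len(bins) > 1 and len(bins[-1]) < min_bin_size:
        bins[-2] = np.concatenate([bins[-2], bins[-1]])
        bins.pop()
    return bins


def seed_connectivity_test(
    graph: PpiGraph,
    seeds: Sequence[str],
    n_perm: int = 1000,
    rng_seed: int = 0,
    min_bin_size: int = 10,
) -> ConnectivityResult:
    """Permutation test of direct connectivity among seed genes.

    Observed statistic: number of graph edges with both endpoints in the
    seed set. Null: seed labels are shuffled within degree bins (pooled to
    >= ``min_bin_size`` nodes). Per-gene p-values compare each seed's count
    of seed neighbours to the same permutations. Reproducible given
    ``rng_seed``.
    """
    seed_set = set(seeds)
    usable = sorted(seed_set & set(graph.node_index))
    dropped = frozenset(seed_set - set(usable))
    if dropped:
        log.info("dropped %d seed(s) absent from the PPI graph", len(dropped))
    if len(usable) < 2:
        raise ValueError("fewer than 2 seed genes present in the graph")

    member = np.zeros(graph.n_nodes, dtype=bool)
    member[[graph.node_index[s] for s in usable]] = True
    u, v = graph.edges[:, 0], graph.edges[:, 1]
    observed = int(np.count_nonzero(member[u] & member[v]))

    rng = np.random.default_rng(rng_seed)
    degrees = graph.degrees()
    connected = np.flatnonzero(degrees > 0)
    # isolated nodes can never contribute an edge: leave their labels fixed so
    # results are invariant to adding isolated nodes to the graph
    bins = _degree_bins(degrees[connected], min_bin_size)
    bins = [connected[b] for b in bins]
    # batched within-bin label permutation: (n_perm, n_nodes) membership matrix
    perm_member = np.tile(member, (n_perm, 1))
    for b in bins:
        labels = member[b]  # within-bin labels to shuffle
        # argsort of random keys -> independent permutation per row
        keys = rng.random((n_perm, len(b)))
        perm_idx = np.argsort(keys, axis=1)
        perm_member[:, b] = labels[perm_idx]

    perm_counts = (perm_member[:, u] & perm_member[:, v]).sum(axis=1)
    p_network = (1 + int(np.count_nonzero(perm_counts >= observed))) / (n_perm + 1)

    # per-gene: seed's number of seed neighbours vs its permuted analogue
    neighbours: dict[int, list[int]] = {}
    for a, b_ in graph.edges:
        neighbours.setdefault(int(a), []).append(int(b_))
        neighbours.setdefault(int(b_), []).append(int(a))
    per_gene_p: dict[str, float] = {}
    for s in usable:
        i = graph.node_index[s]
        nbrs = np.array(neighbours.get(i, []), dtype=np.int64)
        if len(nbrs) == 0:
            per_gene_p[s] = 1.0
            continue
        obs_g = int(np.count_nonzero(member[nbrs]))
        perm_g = perm_member[:, nbrs].sum(axis=1)
        per_gene_p[s] = (1 + int(np.count_nonzero(perm_g >= obs_g))) / (n_perm + 1)

    return ConnectivityResult(
        seed_genes=frozenset(usable),
        direct_edge_count=observed,
        p_network=p_network,
        per_gene_p=per_gene_p,
        n_perm=n_perm,
        dropped_seeds=dropped,
    )
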