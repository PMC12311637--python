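"""Network topology, keystone nodes, attack robustness and efficiency.

Robustness follows the random-attack convention: nodes are removed one
at a time in a uniformly random order; after the i-th removal the
relative size of the largest connected component sigma_i is recorded;
normalized robustness R is the mean of sigma_i over all N steps,
averaged over many random orders, and vulnerability V = 0.5 - R.
R approaches 0.5 for a maximally cohesive graph (complete graph, large
N) and 0 for an edgeless one.

Efficiency follows Latora-Marchiori: nodal efficiency of i is the mean
of 1/d_ij over all other nodes j (0 for unreachable pairs) on the
unweighted graph; global efficiency is the mean over ordered pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from numba import njit
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

__all__ = [
    "topology_metrics",
    "keystone_nodes",
    "random_attack_robustness",
    "efficiency_distribution",
    "RobustnessCurve",
    "EfficiencyDistribution",
]


# ------------------------------------------------------------- topology
def _avg_path_and_diameter(G: nx.Graph) -> tuple[float, float]:
    """Mean shortest-path length over connected pairs; largest finite
    eccentricity."""
    total, pairs, diameter = 0.0, 0, 0
    for source, lengths in nx.all_pairs_shortest_path_length(G):
        finite = [d for t, d in lengths.items() if t != source]
        if finite:
            total += sum(finite)
            pairs += len(finite)
            diameter = max(diameter, max(finite))
    return (total / pairs if pairs else float("nan")), float(diameter)


def _degree_centralization(G: nx.Graph) -> float:
    n = G.number_of_nodes()
    if n < 3:
        return float("nan")
    degrees = np.array([d for _, d in G.degree()])
    return float((degrees.max() - degrees).sum() / ((n - 1) * (n - 2)))


def topology_metrics(
    G: nx.Graph,
    n_null: int = 20,
    louvain_restarts: int = 10,
    seed: int | None = 0,
) -> dict:
    """Standard descriptors of an undirected co-occurrence network.

    Returns modularity (best of ``louvain_restarts`` seeded Louvain
    runs), average path length over connected pairs, average degree,
    diameter, density, clustering coefficient (mean local), Freeman
    degree centralization, and a small-world index
    (C/C_rand)/(L/L_rand) against ``n_null`` Erdos-Renyi G(N, E) graphs
    matched in node and edge count.
    """
    n, e = G.number_of_nodes(), G.number_of_edges()
    if n < 2:
        raise ValueError("need at least 2 nodes")
    rng = np.random.default_rng(seed)

    # signed association weights are not modularity weights: community
    # structure is scored on the unweighted topology
    best_mod = -np.inf
    for _ in range(louvain_restarts):
        comms = nx.community.louvain_communities(
            G, weight=None, resolution=1.0, seed=int(rng.integers(2**31 - 1))
        )
        if e:
            best_mod = max(best_mod, nx.community.modularity(G, comms, weight=None))
        else:
            best_mod = 0.0

    apl, diameter = _avg_path_and_diameter(G)
    clustering = nx.average_clustering(G)

    c_rand, l_rand = [], []
    for _ in range(n_null):
        R = nx.gnm_random_graph(n, e, seed=int(rng.integers(2**31 - 1)))
        c_rand.append(nx.average_clustering(R))
        l_rand.append(_avg_path_and_diameter(R)[0])
    c_rand_mean = float(np.mean(c_rand))
    l_rand_mean = float(np.nanmean(l_rand))
    if c_rand_mean > 0 and l_rand_mean > 0 and not np.isnan(apl):
        small_world = (clustering / c_rand_mean) / (apl / l_rand_mean)
    else:
        small_world = float("nan")

    return {
        "n_nodes": n,
        "n_edges": e,
        "modularity": float(best_mod) if e else 0.0,
        "average_path_length": apl,
        "average_degree": 2 * e / n,
        "diameter": diameter,
        "density": 2 * e / (n * (n - 1)),
        "clustering_coefficient": float(clustering),
        "degree_centralization": _degree_centralization(G),
        "small_world_index": float(small_world),
    }


# ------------------------------------------------------------- keystones
def _nearest_rank_threshold(values: np.ndarray, percentile: float) -> float:
    """Entry threshold of the top (100 - percentile)% of DISTINCT values
    (dense rank): the k-th largest distinct value with
    k = ceil((100 - percentile)/100 * n_distinct)."""
    v = np.unique(np.asarray(values, dtype=float))[::-1]
    k = int(np.ceil((100.0 - percentile) / 100.0 * len(v)))
    k = min(max(k, 1), len(v))
    return float(v[k - 1])


def keystone_nodes(G: nx.Graph, percentile: float = 80.0) -> set:
    """Nodes in the top (100 - percentile)% of BOTH degree and betweenness.

    Percentiles are taken over the distinct values of each centrality
    (dense rank, nearest-rank cutoff) with ties at the threshold
    included: a fully regular graph returns every node, while a star's
    hub is its only keystone.
    """
    if G.number_of_nodes() < 5:
        raise ValueError("need at least 5 nodes")
    nodes = list(G.nodes)
    degree = np.array([G.degree(u) for u in nodes], dtype=float)
    betw_dict = nx.betweenness_centrality(G, normalized=True)
    betw = np.array([betw_dict[u] for u in nodes])
    dthr = _nearest_rank_threshold(degree, percentile)
    bthr = _nearest_rank_threshold(betw, percentile)
    return {u for u, d, b in zip(nodes, degree, betw) if d >= dthr and b >= bthr}


# ------------------------------------------------------------ robustness
@dataclass
class RobustnessCurve:
    n_nodes: int
    sigma: np.ndarray  # mean relative largest-component size after step i (i=1..N)
    robustness: float
    vulnerability: float
    n_iterations: int
    seed: int | None


@njit(cache=False)
def _attack_kernel(n, edge_u, edge_v, orders, sigma_sum):  # pragma: no cover
    """Accumulate largest-component sizes over random removal orders.

    For each order, nodes are added back in reverse with union-find;
    the largest component after the i-th removal equals the largest
    component of the graph induced by the last n - i added nodes.
    """
    n_iter = orders.shape[0]
    n_edges = edge_u.shape[0]
    parent = np.empty(n, dtype=np.int64)
    size = np.empty(n, dtype=np.int64)
    active = np.empty(n, dtype=np.bool_)
    adj_index = np.zeros(n + 1, dtype=np.int64)
    # CSR-ish adjacency over both directions
    deg = np.zeros(n, dtype=np.int64)
    for k in range(n_edges):
        deg[edge_u[k]] += 1
        deg[edge_v[k]] += 1
    for i in range(n):
        adj_index[i + 1] = adj_index[i] + deg[i]
    adj = np.empty(2 * n_edges, dtype=np.int64)
    fill = adj_index[:-1].copy()
    for k in range(n_edges):
        adj[fill[edge_u[k]]] = edge_v[k]
        fill[edge_u[k]] += 1
        adj[fill[edge_v[k]]] = edge_u[k]
        fill[edge_v[k]] += 1

    for it in range(n_iter):
        for i in range(n):
            parent[i] = i
            size[i] = 1
            active[i] = False
        largest = 0
        # add nodes in reverse removal order; sigma after step i uses
        # the graph on nodes orders[it, i:]
        for step in range(n - 1, -1, -1):
            u = orders[it, step]
            active[u] = True
            if largest == 0:
                largest = 1
            for a in range(adj_index[u], adj_index[u + 1]):
                v = adj[a]
                if not active[v]:
                    continue
                ru = u
                while parent[ru] != ru:
                    parent[ru] = parent[parent[ru]]
                    ru = parent[ru]
                rv = v
                while parent[rv] != rv:
                    parent[rv] = parent[parent[rv]]
                    rv = parent[rv]
                if ru != rv:
                    if size[ru] < size[rv]:
                        ru, rv = rv, ru
                    parent[rv] = ru
                    size[ru] += size[rv]
                    if size[ru] > largest:
                        largest = size[ru]
            if step >= 1:
                sigma_sum[step - 1] += largest
        # after removing all n nodes the component size is 0; nothing to add


def random_attack_robustness(
    G: nx.Graph, n_iterations: int = 10_000, seed: int | None = 0
) -> RobustnessCurve:
    """Monte-Carlo random-attack robustness R and vulnerability V = 0.5 - R.

    Per iteration nodes are removed in a uniformly random order; after
    the i-th removal sigma_i is the largest-component size divided by
    the initial node count N.  R = mean over steps and iterations of
    sigma_i (the i = N term is always 0).
    """
    n = G.number_of_nodes()
    if n < 2:
        raise ValueError("need at least 2 nodes")
    nodes = list(G.nodes)
    index = {u: i for i, u in enumerate(nodes)}
    edges = np.array(
        [[index[u], index[v]] for u, v in G.edges() if u != v], dtype=np.int64
    ).reshape(-1, 2)
    rng = np.random.default_rng(seed)
    orders = np.empty((n_iterations, n), dtype=np.int64)
    base = np.arange(n, dtype=np.int64)
    for it in range(n_iterations):
        orders[it] = rng.permutation(base)

    sigma_sum = np.zeros(n, dtype=np.float64)
    _attack_kernel(n, edges[:, 0].copy(), edges[:, 1].copy(), orders, sigma_sum)
    sigma = sigma_sum / (n_iterations * n)  # mean sigma after step i (i=1..N)
    R = float(sigma.sum() / n)
    return RobustnessCurve(
        n_nodes=n,
        sigma=sigma,
        robustness=R,
        vulnerability=0.5 - R,
        n_iterations=n_iterations,
        seed=seed,
    )


# ------------------------------------------------------------ efficiency
@dataclass
class EfficiencyDistribution:
    nodal: np.ndarray  # sorted ascending
    nodal_by_node: dict
    mean: float
    std: float
    global_efficiency: float


def efficiency_distribution(G: nx.Graph) -> EfficiencyDistribution:
    """Latora-Marchiori nodal and global efficiency of an unweighted graph."""
    n = G.number_of_nodes()
    if n < 2:
        raise ValueError("need at least 2 nodes")
    nodes = list(G.nodes)
    A = nx.to_scipy_sparse_array(G, nodelist=nodes, weight=None, format="csr")
    d = shortest_path(csr_matrix(A), method="D", unweighted=True)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    nodal = inv.sum(axis=1) / (n - 1)
    return EfficiencyDistribution(
        nodal=np.sort(nodal),
        nodal_by_node=dict(zip(nodes, nodal)),
        mean=float(nodal.mean()),
        std=float(nodal.std()),
        global_efficiency=float(inv.sum() / (n * (n - 1))),
    )
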