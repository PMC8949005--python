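"""Co-occurrence network construction and topology analysis.

The network stage turns a relative-abundance table into an undirected,
signed OTU association network: Pearson correlations between all OTU pairs
form the association matrix, a correlation threshold (chosen by the
random-matrix-theory scan in :mod:`pomnet.rmt`) defines edges, and the
resulting graph is summarized by the standard topology statistics (average
connectivity avgK = 2L/N, average clustering coefficient, average geodesic
distance over connected pairs), greedy-modularity module partition, and
per-node Zi–Pi roles (network hub / module hub / connector / peripheral).

Degree-preserving Maslov–Sneppen rewiring provides the random null used to
show the observed topology is non-random.

All topology statistics are computed on the sign-ignored simple graph; the
edge sign only enters the positive/negative link tallies.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms.community import greedy_modularity_communities
from networkx.algorithms.community import modularity as nx_modularity

from .exceptions import InsufficientSamplesError
from .otu_table import RelativeAbundanceTable

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationMatrix",
    "EcoNetwork",
    "ModulePartition",
    "NetworkStats",
    "RandomNullSummary",
    "pearson_matrix",
    "build_network",
    "topology_stats",
    "detect_modules",
    "zi_pi",
    "classify_role",
    "role_summary",
    "random_null",
]

#: Zi–Pi role thresholds; both hub-side comparisons are inclusive.
ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62


@dataclass
class AssociationMatrix:
    """Symmetric Pearson correlation matrix over OTU pairs."""

    values: np.ndarray
    otu_ids: list
    n_samples: int

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.otu_ids):
            raise ValueError("matrix shape does not match otu_ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("association matrix must be symmetric")

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)


@dataclass
class EcoNetwork:
    """Undirected signed OTU network at a recorded correlation threshold.

    ``graph`` contains only non-isolated OTUs (nodes with at least one
    surviving edge); ``total_otus`` records how many OTUs entered the
    thresholding, so "total OTUs" and "total nodes" can differ.
    """

    graph: nx.Graph
    threshold: float
    total_otus: int
    taxonomy: pd.Series | None = field(default=None, repr=False)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_links(self) -> int:
        return self.graph.number_of_edges()

    def edge_list(self) -> pd.DataFrame:
        rows = [
            {"source": u, "target": v, "r": d["weight"],
             "sign": "+" if d["sign"] > 0 else "-"}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "r", "sign"])

    def to_graphml(self, path, partition=None, roles=None) -> None:
        """GraphML export with taxonomy/module/Zi/Pi/role node attributes."""
        g = self.graph.copy()
        for node in g.nodes:
            if self.taxonomy is not None and node in self.taxonomy.index:
                g.nodes[node]["taxonomy"] = str(self.taxonomy[node])
            if partition is not None:
                g.nodes[node]["module"] = int(partition.module_of[node])
            if roles is not None and node in roles.index:
                g.nodes[node]["zi"] = float(roles.loc[node, "zi"])
                g.nodes[node]["pi"] = float(roles.loc[node, "pi"])
                g.nodes[node]["role"] = str(roles.loc[node, "role"])
        nx.write_graphml(g, path)


@dataclass
class ModulePartition:
    """Module assignment per node with Newman modularity Q."""

    module_of: dict
    n_modules: int
    modularity: float

    def members(self, module_id: int) -> list:
        return sorted(n for n, m in self.module_of.items() if m == module_id)


@dataclass
class NetworkStats:
    """Topology summary of one network (one Table-style column)."""

    total_otus: int
    total_nodes: int
    total_links: int
    positive_links: int
    negative_links: int
    total_modules: int
    modularity: float
    avg_k: float
    avg_cc: float
    gd: float

    def as_series(self, name: str = "network") -> pd.Series:
        return pd.Series(self.__dict__, name=name)


@dataclass
class RandomNullSummary:
    """Mean ± sd of topology statistics over degree-preserving rewires."""

    n_randomizations: int
    observed: dict
    null_mean: dict
    null_sd: dict
    p_values: dict


def pearson_matrix(table: RelativeAbundanceTable | pd.DataFrame,
                   log10_pseudo: float | None = None) -> AssociationMatrix:
    """Pairwise Pearson r between OTU rows across samples.

    Constant rows (zero variance, correlation undefined) are excluded with
    a warning. Requires at least 3 samples. With ``log10_pseudo`` the
    abundances are transformed to log10(x + pseudo) first (the default
    correlates untransformed proportions).
    """
    df = table.proportions if isinstance(table, RelativeAbundanceTable) else table
    if log10_pseudo is not None:
        if log10_pseudo <= 0:
            raise ValueError("log10_pseudo must be positive")
        df = np.log10(df + log10_pseudo)
    if df.shape[1] < 3:
        raise InsufficientSamplesError(
            f"need >= 3 samples for correlations, got {df.shape[1]}"
        )
    arr = df.to_numpy(dtype=float)
    sd = arr.std(axis=1)
    constant = sd == 0
    if constant.any():
        logger.warning("pearson_matrix: excluding %d constant OTUs: %s",
                       int(constant.sum()),
                       list(df.index[constant][:10]))
        arr = arr[~constant]
        ids = list(df.index[~constant])
    else:
        ids = list(df.index)
    r = np.corrcoef(arr)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return AssociationMatrix(r, ids, df.shape[1])


def build_network(matrix: AssociationMatrix, threshold: float,
                  taxonomy: pd.Series | None = None) -> EcoNetwork:
    """Signed network with an edge wherever |r| ≥ threshold (off-diagonal).

    Isolated OTUs are excluded from the node set. Nodes and edges are
    inserted in sorted order so downstream algorithms are deterministic.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    g = nx.Graph()
    order = np.argsort(np.asarray(matrix.otu_ids, dtype=object))
    ids = [matrix.otu_ids[i] for i in order]
    vals = matrix.values[np.ix_(order, order)]
    n = len(ids)
    for i in range(n):
        for j in range(i + 1, n):
            r = vals[i, j]
            if abs(r) >= threshold:
                g.add_edge(ids[i], ids[j], weight=float(r),
                           sign=1 if r > 0 else -1)
    if g.number_of_edges() == 0:
        logger.warning("build_network: no edge survives threshold %.3f",
                       threshold)
    return EcoNetwork(g, threshold, matrix.n_otus, taxonomy)


def detect_modules(net: EcoNetwork) -> ModulePartition:
    """Greedy agglomerative modularity maximization (sign-ignored graph).

    Communities are merged while the merge with the largest modularity gain
    is positive; Q is Newman's Σ_s (l_s/L − (d_s/2L)²). Module ids are
    assigned by descending size then lexicographic smallest member, so the
    labeling is stable across runs.
    """
    g = net.graph
    if g.number_of_nodes() == 0:
        return ModulePartition({}, 0, 0.0)
    if g.number_of_edges() == 0:
        comms = [{n} for n in sorted(g.nodes)]
    else:
        comms = [set(c) for c in greedy_modularity_communities(g)]
    comms.sort(key=lambda c: (-len(c), str(min(c, key=str))))
    module_of = {node: idx for idx, comm in enumerate(comms) for node in comm}
    q = nx_modularity(g, comms) if g.number_of_edges() else 0.0
    return ModulePartition(module_of, len(comms), float(q))


def _mean_geodesic(g: nx.Graph) -> float:
    """Mean shortest-path length over all connected node pairs."""
    total, pairs = 0, 0
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        if sub.number_of_nodes() < 2:
            continue
        for _, lengths in nx.all_pairs_shortest_path_length(sub):
            total += sum(lengths.values())
            pairs += len(lengths) - 1  # excludes distance-0 self entry
    if pairs == 0:
        return 0.0
    return total / pairs


def topology_stats(net: EcoNetwork,
                   partition: ModulePartition | None = None) -> NetworkStats:
    """Topology statistics of the network (sign-ignored adjacency)."""
    g = net.graph
    n, l = g.number_of_nodes(), g.number_of_edges()
    pos = sum(1 for _, _, d in g.edges(data=True) if d.get("sign", 1) > 0)
    if partition is None:
        partition = detect_modules(net)
    return NetworkStats(
        total_otus=net.total_otus,
        total_nodes=n,
        total_links=l,
        positive_links=pos,
        negative_links=l - pos,
        total_modules=partition.n_modules,
        modularity=partition.modularity,
        avg_k=2 * l / n if n else 0.0,
        avg_cc=nx.average_clustering(g) if n else 0.0,
        gd=_mean_geodesic(g),
    )


def classify_role(zi: float, pi: float) -> str:
    """Four-quadrant Zi–Pi role (hub-side thresholds inclusive)."""
    if zi >= ZI_THRESHOLD:
        return "network hub" if pi >= PI_THRESHOLD else "module hub"
    return "connector" if pi >= PI_THRESHOLD else "peripheral"


def zi_pi(net: EcoNetwork, partition: ModulePartition) -> pd.DataFrame:
    """Within-module degree z-score (Zi) and participation (Pi) per node.

    Zi standardizes a node's within-module degree against the other members
    of its module (0 when the module's within-degrees have zero spread);
    Pi = 1 − Σ_m (k_i,m / k_i)² over modules m. Roles follow the
    four-quadrant rule with thresholds 2.5 / 0.62.
    """
    g = net.graph
    missing = [n for n in g.nodes if n not in partition.module_of]
    if missing:
        raise ValueError(f"partition does not cover nodes: {missing[:5]}")
    # within-module degree of every node
    kin = {
        node: sum(1 for nb in g.neighbors(node)
                  if partition.module_of[nb] == partition.module_of[node])
        for node in g.nodes
    }
    mod_stats = {}
    for mid in set(partition.module_of.values()):
        members = [n for n in g.nodes if partition.module_of[n] == mid]
        ks = np.array([kin[n] for n in members], dtype=float)
        mod_stats[mid] = (ks.mean(), ks.std()) if len(ks) else (0.0, 0.0)
    rows = []
    for node in sorted(g.nodes, key=str):
        k = g.degree(node)
        if k == 0:
            logger.warning("zi_pi: skipping degree-0 node %r", node)
            continue
        mid = partition.module_of[node]
        mean_k, sd_k = mod_stats[mid]
        zi = (kin[node] - mean_k) / sd_k if sd_k > 0 else 0.0
        per_module: dict = {}
        for nb in g.neighbors(node):
            m = partition.module_of[nb]
            per_module[m] = per_module.get(m, 0) + 1
        pi = 1.0 - sum((km / k) ** 2 for km in per_module.values())
        rows.append({"node": node, "module": mid, "degree": k,
                     "zi": zi, "pi": pi, "role": classify_role(zi, pi)})
    df = pd.DataFrame(rows).set_index("node")
    return df


def role_summary(roles: pd.DataFrame) -> pd.Series:
    """Counts per Zi–Pi role, all four roles always present."""
    order = ["network hub", "module hub", "connector", "peripheral"]
    counts = roles["role"].value_counts()
    return counts.reindex(order, fill_value=0)


def _double_edge_swap(g: nx.Graph, n_attempts: int,
                      rng: np.random.Generator) -> int:
    """In-place Maslov–Sneppen rewiring with attempted-swap semantics.

    Each attempt picks two edges (u,v), (x,y) and proposes (u,x), (v,y)
    (after a random orientation flip); proposals creating self-loops or
    parallel edges are rejected. Returns the number of accepted swaps.
    """
    edges = [tuple(e) for e in g.edges()]
    edge_set = {frozenset(e) for e in edges}
    m = len(edges)
    accepted = 0
    if m < 2:
        return 0
    idx = rng.integers(0, m, size=(n_attempts, 2))
    flips = rng.random(n_attempts) < 0.5
    for (i, j), flip in zip(idx, flips):
        if i == j:
            continue
        u, v = edges[i]
        x, y = edges[j]
        if flip:
            x, y = y, x
        if u == x or v == y:
            continue
        e1, e2 = frozenset((u, x)), frozenset((v, y))
        if e1 in edge_set or e2 in edge_set:
            continue
        edge_set.discard(frozenset((u, v)))
        edge_set.discard(frozenset((x, y)))
        edge_set.add(e1)
        edge_set.add(e2)
        edges[i] = (u, x)
        edges[j] = (v, y)
        accepted += 1
    g.remove_edges_from(list(g.edges()))
    g.add_edges_from(edges)
    return accepted


def random_null(net: EcoNetwork, n_rand: int = 100, seed: int = 0,
                swaps_per_link: int = 100) -> RandomNullSummary:
    """Degree-preserving random null for avgCC, GD and modularity.

    Each of ``n_rand`` rewired graphs applies ``swaps_per_link × L``
    attempted double-edge swaps to a copy of the observed graph; the
    observed statistic is compared to the null distribution with the
    (r+1)/(n+1)-corrected two-sided empirical p-value.
    """
    if net.n_links < 2:
        raise ValueError("random null needs a network with >= 2 edges")
    part = detect_modules(net)
    obs = topology_stats(net, part)
    observed = {"avg_cc": obs.avg_cc, "gd": obs.gd,
                "modularity": obs.modularity}
    rng = np.random.default_rng(seed)
    samples: dict = {k: [] for k in observed}
    zero_swap_runs = 0
    for _ in range(n_rand):
        g = nx.Graph()
        g.add_nodes_from(net.graph.nodes)
        g.add_edges_from(net.graph.edges())
        acc = _double_edge_swap(g, swaps_per_link * net.n_links, rng)
        if acc == 0:
            zero_swap_runs += 1
        rnet = EcoNetwork(g, net.threshold, net.total_otus)
        rpart = detect_modules(rnet)
        rstats = topology_stats(rnet, rpart)
        samples["avg_cc"].append(rstats.avg_cc)
        samples["gd"].append(rstats.gd)
        samples["modularity"].append(rstats.modularity)
    if zero_swap_runs == n_rand:
        logger.warning("random_null: graph admits no swap; null equals "
                       "the observed network")
    null_mean, null_sd, p_values = {}, {}, {}
    for key, vals in samples.items():
        arr = np.array(vals)
        null_mean[key] = float(arr.mean())
        null_sd[key] = float(arr.std(ddof=1)) if n_rand > 1 else 0.0
        lo = int((arr <= observed[key]).sum())
        hi = int((arr >= observed[key]).sum())
        p = 2.0 * (min(lo, hi) + 1) / (n_rand + 1)
        p_values[key] = float(min(p, 1.0))
    return RandomNullSummary(n_rand, observed, null_mean, null_sd, p_values)
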