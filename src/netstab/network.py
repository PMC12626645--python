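"""Signed Spearman co-occurrence networks, topology, modules, and node roles.

Edges connect taxa whose Spearman correlation across samples is both strong
(|rho| strictly greater than the threshold, default 0.6) and significant
(two-sided p strictly below the threshold, default 0.01).  Significance uses
the exact permutation distribution of rho for small tie-free samples
(n <= 9) and the t approximation otherwise.  Isolated taxa stay in the node
set: a filtered taxon is part of the community whether or not it correlates
with anything.

Module detection is Louvain greedy modularity maximization on unweighted
edge presence with a fixed seed.  Node roles follow the within-module degree
z-score (Zi) and among-module connectivity / participation coefficient (Pi):
module hubs (Zi >= 2.5, Pi < 0.62), network hubs (Zi >= 2.5, Pi >= 0.62),
connectors (Zi < 2.5, Pi >= 0.62), peripherals (Zi < 2.5, Pi < 0.62).
Non-peripheral nodes are the candidate keystone taxa.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptyResultError, InvalidInputError
from .io import CountTable, relative_abundance

__all__ = [
    "spearman_p_exact",
    "spearman_matrix",
    "SignedNetwork",
    "build_network",
    "topology",
    "ModulePartition",
    "detect_modules",
    "zipi",
    "ROLE_LABELS",
]

ROLE_LABELS = ("peripheral", "connector", "module hub", "network hub")

_EXACT_P_MAX_N = 9


@lru_cache(maxsize=None)
def _exact_null_abs_rho(n: int) -> np.ndarray:
    """Sorted |rho| over all n! rank permutations (tie-free null)."""
    base = np.arange(n, dtype=np.int64)
    perms = np.array(list(itertools.permutations(base)), dtype=np.int64)
    d2 = ((perms - base) ** 2).sum(axis=1)
    rho = 1.0 - 6.0 * d2 / (n * (n**2 - 1))
    return np.sort(np.abs(rho))


def spearman_p_exact(rho: float, n: int) -> float:
    """Two-sided exact permutation p-value for tie-free Spearman rho."""
    null = _exact_null_abs_rho(n)
    k = null.size - np.searchsorted(null, abs(rho) - 1e-12, side="left")
    return k / null.size


def _spearman_p_t(rho: np.ndarray, n: int) -> np.ndarray:
    rho = np.clip(rho, -1 + 1e-15, 1 - 1e-15)
    t = rho * np.sqrt((n - 2) / (1 - rho**2))
    return 2.0 * stats.t.sf(np.abs(t), df=n - 2)


def spearman_matrix(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pairwise Spearman rho and two-sided p over columns.

    Returns ``(rho, p, valid)`` where ``valid`` marks pairs with both
    columns non-constant.  Ties are mid-ranked; exact permutation p-values
    are used for tie-free pairs with n <= 9 samples.
    """
    n, m = values.shape
    ranks = np.apply_along_axis(stats.rankdata, 0, values)
    sd = ranks.std(axis=0)
    constant = sd == 0
    safe = ranks.copy()
    safe[:, constant] = np.arange(n)[:, None]  # placeholder, masked below
    with np.errstate(invalid="ignore"):
        rho = np.corrcoef(safe, rowvar=False)
    rho = np.clip(rho, -1.0, 1.0)
    valid = ~(constant[:, None] | constant[None, :])
    np.fill_diagonal(valid, False)
    p = _spearman_p_t(rho, n)
    if n <= _EXACT_P_MAX_N:
        has_ties = np.array([len(np.unique(values[:, j])) < n for j in range(m)])
        for i in range(m):
            for j in range(i + 1, m):
                if valid[i, j] and not (has_ties[i] or has_ties[j]):
                    p[i, j] = p[j, i] = spearman_p_exact(rho[i, j], n)
    rho[~valid] = 0.0
    p[~valid] = 1.0
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(p, 0.0)
    return rho, p, valid


@dataclass
class SignedNetwork:
    """Undirected taxon graph with signed correlation edges."""

    graph: nx.Graph
    rho_threshold: float = 0.6
    p_threshold: float = 0.01

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {
                "source": u,
                "target": v,
                "rho": d["rho"],
                "p": d["p"],
                "sign": d["sign"],
            }
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "rho", "p", "sign"])

    def node_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "taxon": list(self.graph.nodes),
                "abundance": [self.graph.nodes[t].get("abundance", np.nan) for t in self.graph.nodes],
                "degree": [self.graph.degree(t) for t in self.graph.nodes],
            }
        ).set_index("taxon")

    def abundances(self) -> pd.Series:
        return self.node_table()["abundance"]

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.graph, str(path))

    def write_edge_list(self, path: str | Path) -> None:
        self.edge_table().to_csv(path, sep="\t", index=False)


def build_network(
    table: CountTable,
    rho_threshold: float = 0.6,
    p_threshold: float = 0.01,
    correction: str = "none",
) -> SignedNetwork:
    """Build the signed co-occurrence network from a filtered count table.

    An edge is kept iff |rho| > ``rho_threshold`` (strict) and p (optionally
    Benjamini-Hochberg adjusted with ``correction="bh"``) < ``p_threshold``
    (strict).
    """
    if correction not in ("none", "bh"):
        raise InvalidInputError("correction must be 'none' or 'bh'")
    if table.n_samples < 4:
        raise InvalidInputError("need at least 4 samples to estimate correlations")
    if table.n_samples < 5:
        warnings.warn("fewer than 5 samples: correlations are unreliable", stacklevel=2)
    rel = relative_abundance(table).to_numpy()
    rho, p, valid = spearman_matrix(table.counts.astype(float))
    m = table.n_taxa
    n_constant = int(m - valid.any(axis=1).sum()) if m > 1 else 0
    if n_constant:
        warnings.warn(
            f"{n_constant} constant taxa: their correlations are undefined and skipped",
            stacklevel=2,
        )
    iu = np.triu_indices(m, 1)
    pair_valid = valid[iu]
    pvals = p[iu]
    if correction == "bh":
        adj = np.full_like(pvals, 1.0)
        adj[pair_valid] = stats.false_discovery_control(pvals[pair_valid], method="bh")
        pvals = adj
    keep = pair_valid & (np.abs(rho[iu]) > rho_threshold) & (pvals < p_threshold)

    g = nx.Graph()
    mean_rel = rel.mean(axis=0)
    for j, taxon in enumerate(table.taxon_ids):
        g.add_node(taxon, abundance=float(mean_rel[j]))
    for idx in np.nonzero(keep)[0]:
        i, j = iu[0][idx], iu[1][idx]
        r = float(rho[i, j])
        g.add_edge(
            table.taxon_ids[i],
            table.taxon_ids[j],
            rho=r,
            weight=abs(r),
            p=float(pvals[idx]),
            sign=1 if r > 0 else -1,
        )
    return SignedNetwork(g, rho_threshold, p_threshold)


def _as_graph(net) -> nx.Graph:
    return net.graph if isinstance(net, SignedNetwork) else net


@dataclass(frozen=True)
class ModulePartition:
    """Node -> module assignment with its Newman modularity Q."""

    membership: dict
    modularity: float

    @property
    def n_modules(self) -> int:
        return len(set(self.membership.values()))

    def communities(self) -> list[set]:
        out: dict[int, set] = {}
        for node, mod in self.membership.items():
            out.setdefault(mod, set()).add(node)
        return [out[k] for k in sorted(out)]


def detect_modules(net, resolution: float = 1.0, seed: int = 0) -> ModulePartition:
    """Louvain modularity maximization on unweighted edge presence."""
    g = _as_graph(net)
    if g.number_of_nodes() == 0:
        raise EmptyResultError("empty network")
    if g.number_of_edges() == 0:
        membership = {node: i for i, node in enumerate(g.nodes)}
        return ModulePartition(membership, 0.0)
    comms = nx.community.louvain_communities(
        g, weight=None, resolution=resolution, seed=seed
    )
    comms = sorted((sorted(c) for c in comms), key=lambda c: c[0])
    membership = {node: i for i, comm in enumerate(comms) for node in comm}
    q = nx.community.modularity(g, [set(c) for c in comms], weight=None)
    return ModulePartition(membership, float(q))


def topology(net, partition: ModulePartition | None = None, seed: int = 0) -> dict:
    """Whole-network topological metrics.

    Path length and diameter are unweighted and computed on the largest
    connected component; density, clustering and centralities are over the
    full graph with their standard normalizations.
    """
    g = _as_graph(net)
    n = g.number_of_nodes()
    if n == 0:
        raise EmptyResultError("empty network")
    e = g.number_of_edges()
    if partition is None:
        partition = detect_modules(g, seed=seed) if e else ModulePartition(
            {node: i for i, node in enumerate(g.nodes)}, 0.0
        )
    largest = max(nx.connected_components(g), key=len)
    sub = g.subgraph(largest)
    if sub.number_of_nodes() > 1:
        apl = nx.average_shortest_path_length(sub)
        diam = nx.diameter(sub)
    else:
        apl = 0.0
        diam = 0
    return {
        "n_nodes": n,
        "n_edges": e,
        "mean_degree": 2 * e / n,
        "density": nx.density(g),
        "average_path_length": float(apl),
        "diameter": int(diam),
        "clustering_coefficient": float(nx.average_clustering(g)),
        "modularity": partition.modularity,
        "n_modules": partition.n_modules,
        "mean_betweenness": float(np.mean(list(nx.betweenness_centrality(g).values()))),
        "mean_closeness": float(np.mean(list(nx.closeness_centrality(g).values()))),
        "largest_component_size": len(largest),
    }


def classify_role(zi, pi):
    """Topological role from (Zi, Pi): module/network hub, connector, peripheral."""
    zi = np.asarray(zi, dtype=float)
    pi = np.asarray(pi, dtype=float)
    return np.where(
        zi >= 2.5,
        np.where(pi >= 0.62, "network hub", "module hub"),
        np.where(pi >= 0.62, "connector", "peripheral"),
    )


def zipi(net, partition: ModulePartition) -> pd.DataFrame:
    """Within-module degree z-score (Zi) and participation coefficient (Pi).

    Returns a node table with columns ``zi``, ``pi``, ``role`` and
    ``keystone`` (role != peripheral).
    """
    g = _as_graph(net)
    membership = partition.membership
    missing = [node for node in g.nodes if node not in membership]
    if missing:
        raise InvalidInputError(f"nodes missing from partition: {missing[:5]}")

    nodes = list(g.nodes)
    mod_of = np.array([membership[v] for v in nodes])
    within_deg = np.zeros(len(nodes))
    index = {v: i for i, v in enumerate(nodes)}
    mod_link_counts: list[dict[int, int]] = [dict() for _ in nodes]
    for u, v in g.edges:
        iu, iv = index[u], index[v]
        mu, mv = mod_of[iu], mod_of[iv]
        if mu == mv:
            within_deg[iu] += 1
            within_deg[iv] += 1
        mod_link_counts[iu][mv] = mod_link_counts[iu].get(mv, 0) + 1
        mod_link_counts[iv][mu] = mod_link_counts[iv].get(mu, 0) + 1

    zi = np.zeros(len(nodes))
    for mod in np.unique(mod_of):
        members = mod_of == mod
        k = within_deg[members]
        sd = k.std()
        zi[members] = (k - k.mean()) / sd if sd > 0 else 0.0

    degree = np.array([g.degree(v) for v in nodes], dtype=float)
    pi = np.zeros(len(nodes))
    for i, links in enumerate(mod_link_counts):
        if degree[i] > 0:
            pi[i] = 1.0 - sum((c / degree[i]) ** 2 for c in links.values())

    roles = classify_role(zi, pi)
    return pd.DataFrame(
        {
            "module": mod_of,
            "degree": degree.astype(int),
            "zi": zi,
            "pi": pi,
            "role": roles,
            "keystone": roles != "peripheral",
        },
        index=nodes,
    )
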