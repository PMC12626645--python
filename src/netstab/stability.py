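"""Network stability: robustness, vulnerability, cohesion, keystone removal.

Robustness is measured by a secondary-extinction simulation: a fixed
fraction of nodes is deleted at random, then every survivor's
abundance-weighted mean interaction strength (wMIS) over its surviving
neighbours is recomputed and nodes with wMIS <= 0 are removed
simultaneously, iterating to a fixed point.  The replicate value is the
proportion of the original nodes still present.  Survivors left with no
neighbours have wMIS = 0 and are removed by the <= 0 rule.

Vulnerability is the largest relative drop in global efficiency (mean
inverse shortest-path length, disconnected pairs contributing zero) caused
by deleting a single node.

Cohesion scores each sample as the abundance-weighted sum of its taxa's
connectedness — the mean positive (cooperative) and mean negative
(competitive) null-corrected correlation with the other taxa.  The
negative:positive ratio |neg|/pos summarises how much antagonistic
structure balances the cooperative structure; higher N:P is read as a more
stable community.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse import csgraph

from .errors import InvalidInputError
from .io import CountTable, relative_abundance
from .network import SignedNetwork, _as_graph

__all__ = [
    "global_efficiency",
    "vulnerability",
    "robustness",
    "RobustnessResult",
    "connectedness",
    "cohesion",
    "keystone_removal_test",
    "compare_stability",
    "StabilityReport",
]


def _efficiency_dense(adj: np.ndarray) -> float:
    """Global efficiency from a dense 0/1 adjacency matrix (hop counts)."""
    n = adj.shape[0]
    if n < 2:
        return 0.0
    sp = csgraph.shortest_path(csr_matrix(adj), method="D", unweighted=True)
    with np.errstate(divide="ignore"):
        inv = 1.0 / sp
    inv[~np.isfinite(inv)] = 0.0  # diagonal and disconnected pairs
    return float(inv.sum() / (n * (n - 1)))


def global_efficiency(net) -> float:
    """Mean inverse hop-count shortest-path length over ordered node pairs."""
    g = _as_graph(net)
    if g.number_of_nodes() < 2:
        raise InvalidInputError("global efficiency needs at least 2 nodes")
    return _efficiency_dense(nx.to_numpy_array(g, weight=None))


def vulnerability(net) -> float:
    """Maximum single-node relative contribution to global efficiency."""
    g = _as_graph(net)
    n = g.number_of_nodes()
    if n < 3:
        raise InvalidInputError("vulnerability needs at least 3 nodes")
    adj = nx.to_numpy_array(g, weight=None)
    e_full = _efficiency_dense(adj)
    if e_full == 0:
        return 0.0
    best = -np.inf
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        keep[i] = False
        e_minus = _efficiency_dense(adj[np.ix_(keep, keep)])
        keep[i] = True
        best = max(best, (e_full - e_minus) / e_full)
    return float(best)


@dataclass(frozen=True)
class RobustnessResult:
    """Replicate-level secondary-extinction simulation outcomes."""

    replicates: np.ndarray  # proportion of nodes surviving, one per replicate
    removal_fraction: float

    @property
    def mean(self) -> float:
        return float(self.replicates.mean())

    @property
    def sd(self) -> float:
        return float(self.replicates.std(ddof=1)) if len(self.replicates) > 1 else 0.0


def _cascade(w: np.ndarray, adj: np.ndarray, b: np.ndarray, alive: np.ndarray) -> np.ndarray:
    """Iterate wMIS <= 0 removals to a fixed point; returns final alive mask."""
    alive = alive.copy()
    while alive.any():
        b_alive = b * alive
        num = w @ b_alive
        den = adj @ b_alive
        with np.errstate(invalid="ignore", divide="ignore"):
            wmis = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
        drop = alive & (wmis <= 0)
        if not drop.any():
            break
        alive &= ~drop
    return alive


def robustness(
    net,
    abundances=None,
    removal_fraction: float = 0.5,
    n_reps: int = 100,
    seed: int | None = None,
) -> RobustnessResult:
    """Proportion of taxa persisting after random removal plus cascade.

    ``abundances`` maps every node to a (relative) abundance; when omitted,
    the node ``abundance`` attribute of the network is used.
    """
    g = _as_graph(net)
    if not 0 < removal_fraction < 1:
        raise InvalidInputError("removal_fraction must be in (0, 1)")
    nodes = list(g.nodes)
    n = len(nodes)
    if n == 0:
        raise InvalidInputError("empty network")
    if abundances is None:
        abundances = {v: g.nodes[v].get("abundance") for v in nodes}
    missing = [v for v in nodes if abundances.get(v) is None]
    if missing:
        raise InvalidInputError(f"abundance missing for nodes: {missing[:5]}")
    b = np.array([float(abundances[v]) for v in nodes])
    w = nx.to_numpy_array(g, nodelist=nodes, weight="rho")
    adj = (w != 0).astype(float)

    rng = np.random.default_rng(seed)
    n_remove = int(np.floor(removal_fraction * n))
    values = np.empty(n_reps)
    for r in range(n_reps):
        alive = np.ones(n, dtype=bool)
        alive[rng.choice(n, size=n_remove, replace=False)] = False
        alive = _cascade(w, adj, b, alive)
        values[r] = alive.sum() / n
    return RobustnessResult(values, removal_fraction)


def connectedness(
    table: CountTable,
    null_mode: str = "taxa_shuffle",
    n_shuffle: int = 200,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-taxon positive and negative connectedness.

    Pearson correlations on relative abundances; in ``taxa_shuffle`` mode
    the mean correlation under independent within-column permutations is
    subtracted from the observed value before averaging the positive and
    negative parts per taxon.
    """
    if null_mode not in ("observed", "taxa_shuffle"):
        raise InvalidInputError("null_mode must be 'observed' or 'taxa_shuffle'")
    if table.n_samples < 5:
        raise InvalidInputError("need at least 5 samples")
    rel = relative_abundance(table).to_numpy()
    m = rel.shape[1]
    constant = rel.std(axis=0) == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant taxa: correlations treated as 0",
            stacklevel=2,
        )
    safe = rel.copy()
    if constant.any():
        # placeholder variation so corrcoef stays finite; zeroed below
        safe[:, constant] = np.arange(rel.shape[0])[:, None]
    with np.errstate(invalid="ignore"):
        obs = np.corrcoef(safe, rowvar=False)
    obs[constant, :] = 0.0
    obs[:, constant] = 0.0

    corrected = obs.copy()
    if null_mode == "taxa_shuffle":
        rng = np.random.default_rng(seed)
        acc = np.zeros_like(obs)
        nobs = rel.shape[0]
        for _ in range(n_shuffle):
            shuffled = np.empty_like(safe)
            for j in range(m):
                shuffled[:, j] = safe[rng.permutation(nobs), j]
            c = np.corrcoef(shuffled, rowvar=False)
            acc += c
        null_mean = acc / n_shuffle
        null_mean[constant, :] = 0.0
        null_mean[:, constant] = 0.0
        corrected = obs - null_mean

    pos, neg = _connectedness_from_corr(corrected)
    return pd.DataFrame(
        {"pos_connectedness": pos, "neg_connectedness": neg},
        index=list(table.taxon_ids),
    )


def _connectedness_from_corr(corrected: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean positive / mean negative off-diagonal correlation per taxon."""
    corrected = corrected.copy()
    np.fill_diagonal(corrected, 0.0)
    m = corrected.shape[0]
    pos = np.zeros(m)
    neg = np.zeros(m)
    for i in range(m):
        row = np.delete(corrected[i], i)
        p = row[row > 0]
        q = row[row < 0]
        pos[i] = p.mean() if p.size else 0.0
        neg[i] = q.mean() if q.size else 0.0
    return pos, neg


def cohesion(table: CountTable, conn: pd.DataFrame) -> pd.DataFrame:
    """Per-sample positive/negative cohesion and the N:P ratio.

    cohesion = sum_i abundance_i x connectedness_i over the m taxa of the
    community; N:P = |negative| / positive, NaN when positive cohesion is 0.
    """
    missing = set(table.taxon_ids) - set(conn.index)
    if missing:
        raise InvalidInputError(f"connectedness missing for taxa: {sorted(missing)[:5]}")
    conn = conn.loc[list(table.taxon_ids)]
    rel = relative_abundance(table).to_numpy()
    pos = rel @ conn["pos_connectedness"].to_numpy()
    neg = rel @ conn["neg_connectedness"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(pos > 0, np.abs(neg) / np.where(pos > 0, pos, 1.0), np.nan)
    return pd.DataFrame(
        {"cohesion_pos": pos, "cohesion_neg": neg, "np_ratio": ratio},
        index=list(table.sample_ids),
    )


def keystone_removal_test(net, keystones) -> dict:
    """Vulnerability before and after deleting the keystone node set."""
    g = _as_graph(net)
    keystones = set(keystones)
    unknown = keystones - set(g.nodes)
    if unknown:
        raise InvalidInputError(f"keystones not in network: {sorted(unknown)[:5]}")
    remaining = [v for v in g.nodes if v not in keystones]
    if len(remaining) < 3:
        raise InvalidInputError("fewer than 3 nodes remain after keystone removal")
    v_before = vulnerability(g)
    v_after = vulnerability(g.subgraph(remaining))
    return {
        "v_before": v_before,
        "v_after": v_after,
        "delta_v": v_after - v_before,
        "n_removed": len(keystones),
    }


def compare_stability(a, b, test: str = "welch") -> dict:
    """Two-sample comparison of replicate/per-sample stability vectors.

    ``test="welch"`` is an unequal-variance t-test; ``test="paired"``
    requires equal lengths.  Identical paired vectors return t = 0, p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[~np.isnan(a)] if test == "welch" else a
    b = b[~np.isnan(b)] if test == "welch" else b
    if test == "paired":
        if len(a) != len(b):
            raise InvalidInputError("paired test needs equal-length vectors")
        diffs = a - b
        if np.allclose(diffs.std(ddof=1) if len(diffs) > 1 else 0.0, 0.0):
            t, p = (0.0, 1.0) if np.allclose(diffs, 0) else (np.inf * np.sign(diffs.mean()), 0.0)
            return {"test": test, "t": float(t), "df": len(a) - 1, "p": float(p)}
        t, p = stats.ttest_rel(a, b)
        return {"test": test, "t": float(t), "df": len(a) - 1, "p": float(p)}
    if test != "welch":
        raise InvalidInputError("test must be 'welch' or 'paired'")
    res = stats.ttest_ind(a, b, equal_var=False)
    return {"test": test, "t": float(res.statistic), "df": float(res.df), "p": float(res.pvalue)}


@dataclass(frozen=True)
class StabilityReport:
    """Bundle of the per-network stability metrics."""

    robustness: RobustnessResult
    vulnerability: float
    cohesion: pd.DataFrame  # per sample: cohesion_pos, cohesion_neg, np_ratio

    def summary(self) -> dict:
        return {
            "robustness_mean": self.robustness.mean,
            "robustness_sd": self.robustness.sd,
            "vulnerability": self.vulnerability,
            "np_ratio_mean": float(np.nanmean(self.cohesion["np_ratio"].to_numpy())),
        }
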