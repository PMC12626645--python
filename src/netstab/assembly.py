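"""Phylogenetic and taxonomic null models of community assembly.

The ecological-process partition follows the two-stage null-model framework
of Stegen and colleagues.  For every pair of communities:

* betaMNTD — the abundance-weighted mean phylogenetic distance from each
  taxon to its nearest relative in the paired community;
* betaNTI — the z-score of observed betaMNTD against a null built by
  shuffling taxon labels across the tips of the tree;
* RCbray — the Raup-Crick rank of the observed Bray-Curtis dissimilarity
  within a null distribution of probabilistically re-assembled communities,
  scaled to [-1, 1].

Pairs with betaNTI > 2 are attributed to heterogeneous selection and
betaNTI < -2 to homogeneous selection.  Among the remaining (|betaNTI| <= 2)
pairs, RCbray > 0.95 indicates dispersal limitation, RCbray < -0.95
homogenizing dispersal, and |RCbray| <= 0.95 drift.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .io import CountTable

__all__ = [
    "patristic_matrix",
    "bmntd",
    "bnti",
    "BntiResult",
    "rc_bray",
    "AssemblyPartition",
    "partition_processes",
    "PROCESSES",
]

PROCESSES = (
    "heterogeneous_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "drift",
)


def patristic_matrix(tree: dendropy.Tree, taxon_ids) -> np.ndarray:
    """Tip-to-tip patristic distances, ordered to match ``taxon_ids``."""
    pdm = tree.phylogenetic_distance_matrix()
    by_label = {t.label: t for t in tree.taxon_namespace}
    missing = [t for t in taxon_ids if t not in by_label]
    if missing:
        raise InvalidInputError(f"taxa missing from tree: {missing[:10]}")
    taxa = [by_label[t] for t in taxon_ids]
    m = len(taxa)
    d = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return d


def _weights(table: CountTable, weighted: bool) -> np.ndarray:
    counts = table.counts
    totals = counts.sum(axis=1)
    if np.any(totals == 0):
        raise InvalidInputError("sample with zero total count")
    if weighted:
        return counts / totals[:, None]
    presence = counts > 0
    return presence / presence.sum(axis=1, keepdims=True)


def _bmntd_matrix(d: np.ndarray, weights: np.ndarray, presence: np.ndarray) -> np.ndarray:
    """betaMNTD for all sample pairs given a taxon distance matrix.

    ``nearest[l, i]`` is the distance from taxon i to its nearest taxon
    present in sample l; a taxon present in both communities contributes 0.
    """
    n = weights.shape[0]
    big = np.inf
    nearest = np.empty((n, weights.shape[1]))
    for l in range(n):
        cols = np.nonzero(presence[l])[0]
        nearest[l] = d[:, cols].min(axis=1) if cols.size else big
    out = np.zeros((n, n))
    for k in range(n):
        # 0.5 * (sum_i f_ik * min_{j in l} d_ij + sum_j f_jl * min_{i in k} d_ij)
        out[k] = 0.5 * (nearest @ weights[k] + weights @ nearest[k])
    np.fill_diagonal(out, 0.0)
    return 0.5 * (out + out.T)


def bmntd(table: CountTable, tree: dendropy.Tree, weighted: bool = True) -> pd.DataFrame:
    """Between-community mean nearest taxon distance (betaMNTD)."""
    d = patristic_matrix(tree, table.taxon_ids)
    w = _weights(table, weighted)
    mat = _bmntd_matrix(d, w, table.counts > 0)
    ids = list(table.sample_ids)
    return pd.DataFrame(mat, index=ids, columns=ids)


@dataclass(frozen=True)
class BntiResult:
    """betaNTI z-scores with degeneracy flags (null sd = 0 pairs)."""

    values: pd.DataFrame
    degenerate: pd.DataFrame

    @property
    def matrix(self) -> np.ndarray:
        return self.values.to_numpy()


def bnti(
    table: CountTable,
    tree: dendropy.Tree,
    weighted: bool = True,
    n_null: int = 999,
    seed: int | None = None,
) -> BntiResult:
    """betaNTI: z-score of betaMNTD against a tip-label shuffle null.

    Each null iteration permutes taxon labels across the tree tips (richness
    and abundances preserved), which is equivalent to jointly permuting the
    rows and columns of the patristic matrix.
    """
    if n_null < 99:
        raise InvalidInputError("n_null must be at least 99")
    d = patristic_matrix(tree, table.taxon_ids)
    w = _weights(table, weighted)
    presence = table.counts > 0
    obs = _bmntd_matrix(d, w, presence)
    rng = np.random.default_rng(seed)
    m = d.shape[0]
    acc = np.zeros_like(obs)
    acc2 = np.zeros_like(obs)
    for _ in range(n_null):
        perm = rng.permutation(m)
        null = _bmntd_matrix(d[np.ix_(perm, perm)], w, presence)
        acc += null
        acc2 += null**2
    mean = acc / n_null
    var = np.maximum(acc2 / n_null - mean**2, 0.0)
    sd = np.sqrt(var)
    degenerate = sd <= 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(degenerate, 0.0, (obs - mean) / np.where(degenerate, 1.0, sd))
    np.fill_diagonal(z, 0.0)
    ids = list(table.sample_ids)
    return BntiResult(
        pd.DataFrame(z, index=ids, columns=ids),
        pd.DataFrame(degenerate, index=ids, columns=ids),
    )


def _bray_curtis_counts(x: np.ndarray, y: np.ndarray) -> float:
    tot = x.sum() + y.sum()
    return float(np.abs(x - y).sum() / tot) if tot > 0 else 0.0


def rc_bray(
    table: CountTable,
    n_null: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Raup-Crick metric on Bray-Curtis dissimilarities.

    Null communities preserve each sample's observed richness and total
    abundance: taxa are drawn without replacement with probability
    proportional to occupancy (fraction of samples occupied), and
    individuals are then distributed over the drawn taxa with probability
    proportional to pool-wide relative abundance.  RC is the rank of the
    observed dissimilarity in the null distribution rescaled to [-1, 1].
    """
    counts = table.counts
    totals = counts.sum(axis=1)
    if np.any(totals == 0):
        raise InvalidInputError("sample with zero total count")
    n, m = counts.shape
    rel = counts / totals[:, None]
    obs = np.zeros((n, n))
    for k in range(n):
        obs[k] = np.abs(rel - rel[k]).sum(axis=1) / (rel + rel[k]).sum(axis=1)
    np.fill_diagonal(obs, 0.0)

    occupancy = (counts > 0).mean(axis=0)
    pool_rel = counts.sum(axis=0) / counts.sum()
    occ_p = occupancy / occupancy.sum()
    richness = (counts > 0).sum(axis=1)

    rng = np.random.default_rng(seed)
    below = np.zeros((n, n))
    ties = np.zeros((n, n))
    null_rel = np.empty((n, m))
    for _ in range(n_null):
        null_rel[:] = 0.0
        for k in range(n):
            drawn = rng.choice(m, size=richness[k], replace=False, p=occ_p)
            p = pool_rel[drawn]
            if p.sum() <= 0:
                p = np.full(drawn.size, 1.0 / drawn.size)
            else:
                p = p / p.sum()
            null_rel[k, drawn] = rng.multinomial(totals[k], p) / totals[k]
        for k in range(n):
            d_null = np.abs(null_rel - null_rel[k]).sum(axis=1) / np.maximum(
                (null_rel + null_rel[k]).sum(axis=1), 1e-300
            )
            below[k] += d_null < obs[k]
            ties[k] += d_null == obs[k]
    rc = 2.0 * (below + 0.5 * ties) / n_null - 1.0
    np.fill_diagonal(rc, 0.0)
    rc = 0.5 * (rc + rc.T)
    ids = list(table.sample_ids)
    return pd.DataFrame(rc, index=ids, columns=ids)


@dataclass(frozen=True)
class AssemblyPartition:
    """Five-process partition of community-pair assembly."""

    pair_table: pd.DataFrame  # sample_a, sample_b, bnti, rc, process
    fractions: pd.Series  # indexed by PROCESSES, sums to 1

    def __post_init__(self) -> None:
        total = float(self.fractions.sum())
        if abs(total - 1.0) > 1e-9:
            raise InvalidInputError(f"process fractions sum to {total}, not 1")


def partition_processes(bnti_values, rc_values) -> AssemblyPartition:
    """Classify every sample pair into one of the five assembly processes."""
    b = pd.DataFrame(bnti_values)
    r = pd.DataFrame(rc_values)
    if b.shape != r.shape or list(b.index) != list(r.index):
        raise InvalidInputError("betaNTI and RC matrices cover different pairs")
    ids = list(b.index)
    n = len(ids)
    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            z = float(b.iloc[i, j])
            rc = float(r.iloc[i, j])
            if z > 2:
                proc = "heterogeneous_selection"
            elif z < -2:
                proc = "homogeneous_selection"
            elif rc > 0.95:
                proc = "dispersal_limitation"
            elif rc < -0.95:
                proc = "homogenizing_dispersal"
            else:
                proc = "drift"
            rows.append(
                {"sample_a": ids[i], "sample_b": ids[j], "bnti": z, "rc": rc, "process": proc}
            )
    pairs = pd.DataFrame(rows)
    counts = pairs["process"].value_counts()
    fractions = pd.Series(
        [counts.get(p, 0) / len(pairs) for p in PROCESSES], index=list(PROCESSES)
    )
    return AssemblyPartition(pairs, fractions)
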