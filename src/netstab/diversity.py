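"""Alpha diversity, Bray-Curtis beta diversity, PCoA, and permutation group tests.

Alpha indices follow the conventional definitions: Shannon H = -sum p ln p,
Simpson (Gini-Simpson) = 1 - sum p^2, Pielou evenness J = H / ln(S_obs), and
bias-corrected Chao1 = S_obs + F1(F1-1) / (2(F2+1)) where F1 and F2 are
singleton and doubleton counts.

Bray-Curtis is computed on relative abundances and is a semimetric: the
triangle inequality is not guaranteed and is not asserted anywhere in the
package.  PCoA (classical/Torgerson scaling) keeps negative eigenvalues in
the report but excludes them from the proportion-explained denominator, the
behaviour of the common R implementations.  PERMANOVA (Anderson's pseudo-F
decomposition of squared distances) and ANOSIM (Clarke's rank statistic) use
seeded label permutations with p = (1 + #{perm >= obs}) / (1 + n_perm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform
from scipy import stats
from skbio.stats.distance import DistanceMatrix

from .errors import InvalidInputError
from .io import CountTable, relative_abundance

__all__ = [
    "alpha_diversity",
    "compare_alpha",
    "bray_curtis",
    "pcoa",
    "OrdinationResult",
    "GroupTestResult",
    "permanova",
    "anosim",
]


def alpha_diversity(table: CountTable) -> pd.DataFrame:
    """Per-sample Shannon, Simpson, Pielou and Chao1 indices.

    Pielou is NaN for single-taxon samples (ln S_obs = 0).
    """
    counts = table.counts
    if np.any(counts.sum(axis=1) == 0):
        raise InvalidInputError("empty sample (zero total count)")
    rel = counts / counts.sum(axis=1, keepdims=True)
    safe = np.where(rel > 0, rel, 1.0)  # log(1) = 0 for absent taxa
    shannon = -(rel * np.log(safe)).sum(axis=1)
    simpson = 1.0 - (rel**2).sum(axis=1)
    s_obs = (counts > 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        pielou = np.where(s_obs > 1, shannon / np.log(np.maximum(s_obs, 2)), np.nan)
    f1 = (counts == 1).sum(axis=1)
    f2 = (counts == 2).sum(axis=1)
    chao1 = s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    return pd.DataFrame(
        {"shannon": shannon, "simpson": simpson, "pielou": pielou, "chao1": chao1},
        index=list(table.sample_ids),
    )


def compare_alpha(
    alpha: pd.DataFrame, groups: pd.Series, equal_var: bool = False
) -> pd.DataFrame:
    """Pairwise two-sample t-tests per alpha index between groups.

    Welch's test by default (``equal_var=False``); set ``equal_var=True``
    for Student's.
    """
    groups = groups.loc[alpha.index]
    labels = list(pd.unique(groups))
    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            for metric in alpha.columns:
                x = alpha.loc[groups == a, metric].dropna()
                y = alpha.loc[groups == b, metric].dropna()
                t, p = stats.ttest_ind(x, y, equal_var=equal_var)
                rows.append(
                    {"group_a": a, "group_b": b, "metric": metric, "t": t, "p": p}
                )
    return pd.DataFrame(rows)


def bray_curtis(table: CountTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between samples, on relative abundances."""
    rel = relative_abundance(table).to_numpy()
    n = rel.shape[0]
    d = np.zeros((n, n))
    for j in range(n):
        diff = np.abs(rel - rel[j]).sum(axis=1)
        tot = (rel + rel[j]).sum(axis=1)
        d[:, j] = np.where(tot > 0, diff / tot, 0.0)
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids=list(table.sample_ids))


@dataclass(frozen=True)
class OrdinationResult:
    """Classical-scaling ordination of a distance matrix."""

    eigenvalues: np.ndarray  # all eigenvalues, descending (may be negative)
    coordinates: pd.DataFrame  # samples x retained positive axes
    proportion_explained: np.ndarray  # over positive eigenvalues only


def pcoa(d: DistanceMatrix, eps: float = 1e-10) -> OrdinationResult:
    """Principal coordinate analysis by Gower double-centering.

    Axes with eigenvalue <= ``eps * max(eig)`` are dropped from the
    coordinates; negative eigenvalues are reported but excluded from the
    proportion-explained denominator.
    """
    a = -0.5 * np.asarray(d.data) ** 2
    n = a.shape[0]
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    b = a - row - col + a.mean()
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > eps * max(eigval.max(), eps)
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    pos_sum = eigval[eigval > 0].sum()
    prop = np.where(eigval > 0, eigval / pos_sum, 0.0) if pos_sum > 0 else np.zeros(n)
    frame = pd.DataFrame(
        coords, index=list(d.ids), columns=[f"PCo{i+1}" for i in range(coords.shape[1])]
    )
    return OrdinationResult(eigval, frame, prop)


@dataclass(frozen=True)
class GroupTestResult:
    """Result of a distance-matrix permutation test."""

    method: str
    statistic: float  # pseudo-F (PERMANOVA) or R (ANOSIM)
    r_squared: float | None  # PERMANOVA effect size; None for ANOSIM
    p_value: float
    n_permutations: int
    seed: int | None


def _check_groups(d: DistanceMatrix, groups: np.ndarray) -> None:
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise InvalidInputError("need at least 2 groups")
    if np.any(counts < 2):
        small = labels[counts < 2][0]
        raise InvalidInputError(f"group {small!r} has fewer than 2 samples")
    if len(groups) != len(d.ids):
        raise InvalidInputError("group labels do not match distance matrix")


def _permanova_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.nonzero(codes == g)[0]
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    df_between = n_groups - 1
    df_within = n - n_groups
    f = (ss_between / df_between) / (ss_within / df_within) if ss_within > 0 else np.inf
    r2 = ss_between / ss_total if ss_total > 0 else 0.0
    return f, r2


def permanova(
    d: DistanceMatrix,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
) -> GroupTestResult:
    """One-way PERMANOVA on a distance matrix."""
    groups = np.asarray(list(groups))
    _check_groups(d, groups)
    codes = pd.factorize(groups)[0]
    k = codes.max() + 1
    d2 = np.asarray(d.data) ** 2
    f_obs, r2 = _permanova_f(d2, codes, k)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        f_perm, _ = _permanova_f(d2, rng.permutation(codes), k)
        if f_perm >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return GroupTestResult("permanova", float(f_obs), float(r2), p, n_perm, seed)


def _anosim_r(rank_cond: np.ndarray, within_mask: np.ndarray, n: int) -> float:
    r_within = rank_cond[within_mask].mean()
    r_between = rank_cond[~within_mask].mean()
    return (r_between - r_within) / (n * (n - 1) / 4.0)


def anosim(
    d: DistanceMatrix,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
) -> GroupTestResult:
    """ANOSIM: Clarke's rank-based R statistic with a permutation p-value."""
    groups = np.asarray(list(groups))
    _check_groups(d, groups)
    codes = pd.factorize(groups)[0]
    n = len(codes)
    cond = squareform(np.asarray(d.data), checks=False)
    ranks = stats.rankdata(cond)
    iu = np.triu_indices(n, 1)
    within = codes[iu[0]] == codes[iu[1]]
    r_obs = _anosim_r(ranks, within, n)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        within_p = perm[iu[0]] == perm[iu[1]]
        if _anosim_r(ranks, within_p, n) >= r_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return GroupTestResult("anosim", float(r_obs), None, p, n_perm, seed)
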