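"""Synthetic datasets with the statistical structure the pipeline assumes.

The generator emulates a processed amplicon survey of gut microbial
communities: four host-by-condition groups of 21 samples each, compositional
counts with a log-normal abundance spectrum, a block-modular latent
correlation structure among taxa (the substrate for co-occurrence network
inference), taxa living on a simulated phylogeny, and environmental
covariates wired to a response through known standardized path
coefficients.  Every draw flows from an explicit seed, and the ground truth
(module membership, intended edge signs, assembly regime, path weights) is
recorded so downstream stages can be tested against it.

Counts are produced by a latent multivariate normal with the block
covariance, exponentiated to log-normal intensities and closed
compositionally by a per-sample multinomial draw at fixed sequencing depth.
The multinomial closure matches amplicon data and induces a mild negative
correlation bias; that bias is part of what the downstream analysis sees,
exactly as with real compositional counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .errors import GenerationError, InvalidInputError
from .io import CountTable

__all__ = [
    "SynthConfig",
    "SynthTruth",
    "simulate_tree",
    "simulate_counts",
    "simulate_assembly",
    "simulate_env",
    "simulate_dataset",
]

ASSEMBLY_REGIMES = ("selection", "dispersal_limitation", "drift")

#: spread (sd of log base abundance) of the taxon abundance spectrum
_BASE_LOG_SD = 0.5


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the block-modular compositional count generator.

    Defaults mirror the emulated study design: 4 groups x 21 samples,
    300 taxa in 3 latent modules with strong within-module correlation.
    """

    n_samples_per_group: int = 21
    n_groups: int = 4
    n_taxa: int = 300
    n_modules: int = 3
    within_module_rho: float = 0.8
    between_module_rho: float = 0.0
    neg_edge_fraction: float = 0.3
    sequencing_depth: int = 50_000
    lognormal_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples_per_group", "n_groups", "n_taxa", "n_modules",
                     "sequencing_depth"):
            if getattr(self, name) < 1:
                raise InvalidInputError(f"{name} must be >= 1")
        for name in ("within_module_rho", "between_module_rho"):
            if not -1 <= getattr(self, name) <= 1:
                raise InvalidInputError(f"{name} must lie in [-1, 1]")
        if not 0 <= self.neg_edge_fraction <= 1:
            raise InvalidInputError("neg_edge_fraction must lie in [0, 1]")
        if self.lognormal_sigma <= 0:
            raise InvalidInputError("lognormal_sigma must be positive")
        if self.n_modules > self.n_taxa:
            raise InvalidInputError("n_modules cannot exceed n_taxa")

    @property
    def n_samples(self) -> int:
        return self.n_samples_per_group * self.n_groups

    def group_labels(self) -> list[str]:
        names = ["NCH", "CH", "NCF", "CF"]
        if self.n_groups <= 4:
            return names[: self.n_groups]
        return names + [f"G{i}" for i in range(5, self.n_groups + 1)]


@dataclass(frozen=True)
class SynthTruth:
    """Ground truth recorded by the generator."""

    module_of_taxon: dict = field(default_factory=dict)
    true_edges: tuple = ()  # (taxon_a, taxon_b, sign)
    assembly_regime: str | None = None
    path_coefficients: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)  # regime internals (traits, optima, ...)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "module_of_taxon": self.module_of_taxon,
            "true_edges": [list(e) for e in self.true_edges],
            "assembly_regime": self.assembly_regime,
            "path_coefficients": {f"{a}->{b}": v for (a, b), v in self.path_coefficients.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _taxon_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"OTU_{i+1:0{width}d}" for i in range(n)]


def simulate_tree(n_taxa: int, seed: int = 0) -> dendropy.Tree:
    """Pure-birth (Yule) tree with unit birth rate, rescaled to height 1.

    Tips are labelled ``OTU_0001`` ... in birth order; branch lengths are
    strictly positive and the tree is ultrametric.  Identical seeds yield
    byte-identical Newick strings.
    """
    if n_taxa < 2:
        raise InvalidInputError("n_taxa must be at least 2")
    rng = np.random.default_rng(seed)

    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    birth_time = {root: 0.0}
    active = [root]
    t = 0.0
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / len(active))
        idx = int(rng.integers(len(active)))
        parent = active.pop(idx)
        children = []
        for _ in range(2):
            child = dendropy.Node()
            parent.add_child(child)
            birth_time[child] = t
            children.append(child)
        active.extend(children)
    t_end = t + rng.exponential(1.0 / len(active))

    labels = _taxon_ids(n_taxa)
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon = taxa.new_taxon(labels[i])
    for node in tree.preorder_node_iter():
        if node is root:
            node.edge.length = None
            continue
        end = t_end if node.is_leaf() else min(birth_time[c] for c in node.child_nodes())
        node.edge.length = (end - birth_time[node]) / t_end  # rescale height to 1
    return tree


def _block_covariance(cfg: SynthConfig, signs: np.ndarray, modules: np.ndarray) -> np.ndarray:
    same = modules[:, None] == modules[None, :]
    rho = np.where(same, cfg.within_module_rho, cfg.between_module_rho)
    cov = np.outer(signs, signs) * rho
    np.fill_diagonal(cov, 1.0)
    return cov


def _repair_psd(cov: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Clip negative eigenvalues to 1e-10, renormalize to unit diagonal.

    Returns the repaired correlation matrix and a factor L with
    cov = L L^T for sampling.
    """
    eigval, eigvec = np.linalg.eigh(cov)
    if eigval.min() < -1e-8:
        eigval = np.clip(eigval, 1e-10, None)
        cov = (eigvec * eigval) @ eigvec.T
        d = np.sqrt(np.diag(cov))
        cov = cov / np.outer(d, d)
        eigval, eigvec = np.linalg.eigh(cov)
    if eigval.min() < -1e-8:
        raise GenerationError("covariance not PSD after repair")
    eigval = np.clip(eigval, 0.0, None)
    factor = eigvec * np.sqrt(eigval)
    return cov, factor


def _negation_counts(size: int, target_fraction: float) -> int:
    """Number of negated taxa in a module of ``size`` so that the fraction
    of sign-discordant within-module pairs best matches the target."""
    if size < 2 or target_fraction <= 0:
        return 0
    pairs = size * (size - 1) / 2
    best_k, best_err = 0, target_fraction
    for k in range(size + 1):
        frac = k * (size - k) / pairs
        err = abs(frac - target_fraction)
        if err < best_err:
            best_k, best_err = k, err
    return best_k


def simulate_counts(cfg: SynthConfig) -> tuple[CountTable, SynthTruth]:
    """Block-modular compositional counts with recorded ground truth."""
    rng = np.random.default_rng(cfg.seed)
    m = cfg.n_taxa
    modules = (np.arange(m) * cfg.n_modules) // m  # contiguous blocks
    signs = np.ones(m)
    for mod in range(cfg.n_modules):
        members = np.nonzero(modules == mod)[0]
        k = _negation_counts(len(members), cfg.neg_edge_fraction)
        signs[members[:k]] = -1.0

    cov = _block_covariance(cfg, signs, modules)
    _, factor = _repair_psd(cov)

    n = cfg.n_samples
    z = rng.standard_normal((n, m)) @ factor.T
    mu = rng.normal(0.0, _BASE_LOG_SD, size=m)
    intensity = np.exp(mu + cfg.lognormal_sigma * z)
    probs = intensity / intensity.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(cfg.sequencing_depth, p) for p in probs])

    taxa = _taxon_ids(m)
    samples = [f"S{i+1:03d}" for i in range(n)]
    table = CountTable(counts, tuple(samples), tuple(taxa))

    edges = []
    for mod in range(cfg.n_modules):
        members = np.nonzero(modules == mod)[0]
        for a_pos, i in enumerate(members):
            for j in members[a_pos + 1 :]:
                edges.append((taxa[i], taxa[j], int(signs[i] * signs[j])))
    truth = SynthTruth(
        module_of_taxon={taxa[i]: int(modules[i]) for i in range(m)},
        true_edges=tuple(edges),
    )
    return table, truth


def _brownian_traits(tree: dendropy.Tree, taxon_ids, rng: np.random.Generator) -> np.ndarray:
    trait = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent = node.parent_node
        bl = node.edge.length or 0.0
        trait[node] = trait[parent] + rng.normal(0.0, np.sqrt(max(bl, 1e-12)))
    by_label = {leaf.taxon.label: trait[leaf] for leaf in tree.leaf_node_iter()}
    return np.array([by_label[t] for t in taxon_ids])


def simulate_assembly(
    regime: str,
    n_communities: int,
    n_taxa: int,
    seed: int = 0,
    depth: int = 5_000,
) -> tuple[CountTable, dendropy.Tree, SynthTruth]:
    """Communities assembled under a known ecological regime.

    * ``selection`` — a Brownian trait evolves on the tree; communities
      filter the regional pool by distance between the trait and their
      environmental optimum.  Communities alternate between two contrasting
      optima, so between-optimum pairs experience heterogeneous selection.
    * ``dispersal_limitation`` — each community is colonized from a
      spatially restricted, phylogeny-independent window of the pool;
      with ``n_communities`` dividing the pool evenly the windows are
      disjoint.
    * ``drift`` — plain multinomial draws from the regional pool.
    """
    if regime not in ASSEMBLY_REGIMES:
        raise InvalidInputError(f"unknown regime {regime!r}; use one of {ASSEMBLY_REGIMES}")
    if n_communities < 2:
        raise InvalidInputError("need at least 2 communities")
    rng = np.random.default_rng(seed)
    tree = simulate_tree(n_taxa, seed=seed)
    taxa = _taxon_ids(n_taxa)
    pool = np.exp(rng.normal(0.0, _BASE_LOG_SD, size=n_taxa))
    pool_p = pool / pool.sum()

    counts = np.zeros((n_communities, n_taxa), dtype=np.int64)
    extras: dict = {}
    if regime == "drift":
        for k in range(n_communities):
            counts[k] = rng.multinomial(depth, pool_p)
    elif regime == "selection":
        traits = _brownian_traits(tree, taxa, rng)
        sd = traits.std() or 1.0
        optima = (traits.mean() - sd, traits.mean() + sd)
        width = 0.5 * sd
        extras = {"traits": traits.tolist(), "optima": list(optima)}
        for k in range(n_communities):
            opt = optima[k % 2]
            weight = np.exp(-((traits - opt) ** 2) / (2 * width**2))
            p = pool_p * weight
            counts[k] = rng.multinomial(depth, p / p.sum())
    else:  # dispersal_limitation
        order = rng.permutation(n_taxa)  # spatial arrangement independent of phylogeny
        window = max(2, n_taxa // n_communities)
        for k in range(n_communities):
            lo = (k * window) % n_taxa
            idx = order[[(lo + i) % n_taxa for i in range(window)]]
            p = np.zeros(n_taxa)
            p[idx] = pool_p[idx]
            counts[k] = rng.multinomial(depth, p / p.sum())

    samples = [f"C{k+1:03d}" for k in range(n_communities)]
    table = CountTable(counts, tuple(samples), tuple(taxa))
    return table, tree, SynthTruth(assembly_regime=regime, extras=extras)


def _normalize_path_coefficients(path_coefficients) -> dict:
    out = {}
    for key, value in dict(path_coefficients).items():
        if isinstance(key, str):
            if "->" not in key:
                raise InvalidInputError(f"path key {key!r} must be 'source->sink'")
            a, b = (s.strip() for s in key.split("->", 1))
        else:
            a, b = key
        out[(a, b)] = float(value)
    return out


def simulate_env(
    n_samples: int,
    path_coefficients,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Linear-Gaussian data from a directed acyclic path specification.

    Exogenous variables are standard normal; each endogenous variable is
    the stated linear combination of its parents plus N(0, noise_sd)
    noise.  All columns are returned z-scored.
    """
    import networkx as nx

    coeffs = _normalize_path_coefficients(path_coefficients)
    dag = nx.DiGraph()
    for (a, b), w in coeffs.items():
        dag.add_edge(a, b, weight=w)
    if dag.number_of_nodes() == 0:
        raise InvalidInputError("no variables in path specification")
    if not nx.is_directed_acyclic_graph(dag):
        raise InvalidInputError(f"cyclic path specification: {nx.find_cycle(dag)}")
    if noise_sd < 0:
        raise InvalidInputError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    values: dict[str, np.ndarray] = {}
    for node in nx.topological_sort(dag):
        parents = list(dag.predecessors(node))
        if not parents:
            values[node] = rng.standard_normal(n_samples)
        else:
            signal = sum(coeffs[(p, node)] * values[p] for p in parents)
            values[node] = signal + noise_sd * rng.standard_normal(n_samples)
    df = pd.DataFrame(values, index=[f"S{i+1:03d}" for i in range(n_samples)])
    sd = df.std(ddof=1).replace(0, 1.0)
    return (df - df.mean()) / sd


#: default environment wiring used by :func:`simulate_dataset`
DEFAULT_ENV_PATHS = {("WT", "MCs"): 0.5, ("MCs", "stability"): -0.52}


def simulate_dataset(
    cfg: SynthConfig,
    outdir: str | Path | None = None,
    env_paths=None,
    env_noise_sd: float = 0.8,
):
    """Full study-shaped dataset: counts, metadata, tree, environment, truth.

    Returns ``(table, metadata, tree, env, truth)``; when ``outdir`` is
    given, also writes counts/metadata/env as TSV, the tree as Newick and
    the truth sidecar as JSON.
    """
    table, truth = simulate_counts(cfg)
    tree = simulate_tree(cfg.n_taxa, seed=cfg.seed + 1)
    groups = np.repeat(cfg.group_labels(), cfg.n_samples_per_group)
    metadata = pd.DataFrame({"group": groups}, index=list(table.sample_ids))
    paths = _normalize_path_coefficients(
        DEFAULT_ENV_PATHS if env_paths is None else env_paths
    )
    env = simulate_env(cfg.n_samples, paths, noise_sd=env_noise_sd, seed=cfg.seed + 2)
    env.index = list(table.sample_ids)
    truth = SynthTruth(
        module_of_taxon=truth.module_of_taxon,
        true_edges=truth.true_edges,
        path_coefficients=paths,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.write_tsv(outdir / "counts.tsv")
        metadata.to_csv(outdir / "metadata.tsv", sep="\t", index_label="sample_id")
        env.to_csv(outdir / "env.tsv", sep="\t", index_label="sample_id")
        (outdir / "tree.nwk").write_text(tree.as_string(schema="newick"))
        truth.to_json(outdir / "truth.json")
    return table, metadata, tree, env, truth
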