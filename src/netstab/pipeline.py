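"""End-to-end per-group orchestration of the analysis pipeline.

Stage order mirrors the analysis the package implements: taxon screening,
diversity and ordination statistics across groups, assembly null models,
signed co-occurrence network construction, stability metrics and keystone
tests per group, and driver analysis (keystone importance, environmental
forward selection, standardized path model).

Each group is analysed independently — its own filter, its own network —
and only the diversity permutation tests and the stability comparisons look
across groups.  Every stage draws its randomness from a seed derived
deterministically from the master seed and the stage name, so a rerun with
the same configuration reproduces every output byte for byte.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assembly as asm
from . import diversity as dv
from . import drivers as drv
from . import io as nio
from . import network as net
from . import stability as stb
from .errors import InvalidInputError, NetstabError

__all__ = ["RunConfig", "run_pipeline", "derive_seed", "PipelineError"]


class PipelineError(NetstabError):
    """A stage failed; carries the stage name and context."""

    def __init__(self, stage: str, context: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed ({context}): {cause}")
        self.stage = stage
        self.cause = cause


def derive_seed(master_seed: int, *parts: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    key = ":".join([str(master_seed), *parts]).encode()
    return zlib.crc32(key) & 0x7FFFFFFF


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Numeric defaults are the analysis defaults throughout the package:
    0.1% mean relative abundance and strictly > 1/3 prevalence for the
    taxon screen, |rho| > 0.6 and p < 0.01 for edges, 50% random removal
    with 100 replicates for robustness, 999 permutations/nulls for the
    permutation tests and null models.
    """

    counts: str
    metadata: str
    outdir: str
    tree: str | None = None
    env: str | None = None
    group_column: str = "group"
    min_mean_rel_abund: float = 0.001
    min_prevalence: float = 1.0 / 3.0
    rho_threshold: float = 0.6
    p_threshold: float = 0.01
    p_correction: str = "none"
    removal_fraction: float = 0.5
    robustness_reps: int = 100
    n_shuffle: int = 200
    n_perm: int = 999
    n_null: int = 999
    rc_null: int = 999
    rf_trees: int = 500
    rf_perm: int = 100
    forward_alpha: float = 0.05
    path_equations: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.removal_fraction < 1:
            raise InvalidInputError("removal_fraction must be in (0, 1)")
        if not 0 <= self.min_prevalence < 1:
            raise InvalidInputError("min_prevalence must be in [0, 1)")
        if not 0 < self.p_threshold <= 1:
            raise InvalidInputError("p_threshold must be in (0, 1]")
        if self.rho_threshold < 0 or self.rho_threshold >= 1:
            raise InvalidInputError("rho_threshold must be in [0, 1)")
        for name in ("robustness_reps", "n_shuffle", "n_perm", "rf_trees", "rf_perm"):
            if getattr(self, name) < 1:
                raise InvalidInputError(f"{name} must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


class _Log:
    def __init__(self) -> None:
        self.lines: list[str] = []

    def write(self, msg: str) -> None:
        self.lines.append(msg)

    def dump(self, path: Path) -> None:
        path.write_text("\n".join(self.lines) + "\n")


def _run_stage(log: _Log, stage: str, context: str, fn, outdir: Path):
    try:
        return fn()
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage={stage}\ncontext={context}\nerror={exc}\n")
        log.write(f"FAILED stage={stage} context={context} error={exc}")
        raise PipelineError(stage, context, exc) from exc


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage for every group; returns the summary dict.

    Writes per-group TSV/GraphML outputs plus ``summary.json`` and
    ``run.log`` under ``cfg.outdir``.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = _Log()
    log.write(f"netstab pipeline; master_seed={cfg.seed}")
    for key, value in sorted(vars(cfg).items()):
        log.write(f"param {key} = {value}")

    table = _run_stage(log, "io", cfg.counts, lambda: nio.read_count_table(cfg.counts), outdir)
    meta = _run_stage(
        log, "io", cfg.metadata,
        lambda: nio.read_metadata(cfg.metadata, cfg.group_column), outdir,
    )
    groups = meta.groups_for(table.sample_ids)
    tree = None
    if cfg.tree:
        tree = _run_stage(
            log, "io", cfg.tree, lambda: nio.read_tree(cfg.tree, table.taxon_ids), outdir
        )
    env = None
    if cfg.env:
        env = _run_stage(
            log, "io", cfg.env,
            lambda: pd.read_csv(cfg.env, sep="\t", index_col=0), outdir,
        )
    log.write(f"counts: {table.n_samples} samples x {table.n_taxa} taxa; "
              f"groups: {dict(groups.value_counts().sort_index())}")

    summary: dict = {"seed": cfg.seed, "groups": {}}

    # ---- diversity across all samples -----------------------------------
    def _diversity():
        alpha = dv.alpha_diversity(table)
        alpha.to_csv(outdir / "alpha_diversity.tsv", sep="\t", index_label="sample_id")
        tests = dv.compare_alpha(alpha, groups)
        tests.to_csv(outdir / "alpha_tests.tsv", sep="\t", index=False)
        bc = dv.bray_curtis(table)
        pd.DataFrame(bc.data, index=bc.ids, columns=bc.ids).to_csv(
            outdir / "bray_curtis.tsv", sep="\t", index_label="sample_id"
        )
        ord_res = dv.pcoa(bc)
        ord_res.coordinates.to_csv(outdir / "pcoa_coordinates.tsv", sep="\t",
                                   index_label="sample_id")
        seed_d = derive_seed(cfg.seed, "diversity")
        perm = dv.permanova(bc, groups, n_perm=cfg.n_perm, seed=seed_d)
        anos = dv.anosim(bc, groups, n_perm=cfg.n_perm, seed=seed_d + 1)
        return {
            "permanova": {"pseudo_f": perm.statistic, "r2": perm.r_squared, "p": perm.p_value},
            "anosim": {"r": anos.statistic, "p": anos.p_value},
            "pcoa_prop_explained_1_2": list(np.round(ord_res.proportion_explained[:2], 6)),
        }

    summary["diversity"] = _run_stage(log, "diversity", "all samples", _diversity, outdir)
    log.write("diversity: done")

    # ---- per-group stages ------------------------------------------------
    robustness_reps: dict[str, np.ndarray] = {}
    np_ratio: dict[str, pd.Series] = {}
    group_order = list(pd.unique(groups))
    for group in group_order:
        gdir = outdir / f"group_{group}"
        gdir.mkdir(exist_ok=True)
        sample_ids = [s for s, g in zip(table.sample_ids, groups) if g == group]
        gtable = table.select_samples(sample_ids)
        gsum: dict = {"n_samples": len(sample_ids)}

        def _filter(gtable=gtable):
            return nio.filter_taxa(gtable, cfg.min_mean_rel_abund, cfg.min_prevalence)

        ftable = _run_stage(log, "filter", group, _filter, gdir)
        ftable.write_tsv(gdir / "filtered_counts.tsv")
        gsum["n_taxa_filtered"] = ftable.n_taxa
        log.write(f"[{group}] filter: {gtable.n_taxa} -> {ftable.n_taxa} taxa")

        def _network(ftable=ftable):
            return net.build_network(ftable, cfg.rho_threshold, cfg.p_threshold,
                                     cfg.p_correction)

        network = _run_stage(log, "network", group, _network, gdir)
        network.write_edge_list(gdir / "edges.tsv")
        network.write_graphml(gdir / "network.graphml")
        seed_mod = derive_seed(cfg.seed, "modules", group)
        partition = net.detect_modules(network, seed=seed_mod)
        topo = net.topology(network, partition=partition)
        gsum["network"] = topo
        pd.Series(topo).to_csv(gdir / "topology.tsv", sep="\t", header=False)
        roles = net.zipi(network, partition)
        roles.to_csv(gdir / "node_roles.tsv", sep="\t", index_label="taxon")
        keystones = list(roles.index[roles["keystone"]])
        gsum["n_keystones"] = len(keystones)
        log.write(f"[{group}] network: {topo['n_nodes']} nodes, {topo['n_edges']} edges, "
                  f"{len(keystones)} keystones")

        def _stability(ftable=ftable, network=network, group=group):
            seed_r = derive_seed(cfg.seed, "robustness", group)
            rob = stb.robustness(network, removal_fraction=cfg.removal_fraction,
                                 n_reps=cfg.robustness_reps, seed=seed_r)
            vul = stb.vulnerability(network)
            seed_c = derive_seed(cfg.seed, "cohesion", group)
            conn = stb.connectedness(ftable, n_shuffle=cfg.n_shuffle, seed=seed_c)
            coh = stb.cohesion(ftable, conn)
            return stb.StabilityReport(rob, vul, coh)

        report = _run_stage(log, "stability", group, _stability, gdir)
        pd.DataFrame({"replicate": np.arange(1, cfg.robustness_reps + 1),
                      "surviving_fraction": report.robustness.replicates}).to_csv(
            gdir / "robustness_replicates.tsv", sep="\t", index=False)
        report.cohesion.to_csv(gdir / "cohesion.tsv", sep="\t", index_label="sample_id")
        gsum["stability"] = report.summary()
        robustness_reps[group] = report.robustness.replicates
        np_ratio[group] = report.cohesion["np_ratio"]
        log.write(f"[{group}] stability: robustness {report.robustness.mean:.4f} "
                  f"+/- {report.robustness.sd:.4f}, vulnerability {report.vulnerability:.4f}")

        if keystones and network.n_nodes - len(keystones) >= 3:
            krt = _run_stage(
                log, "keystone_removal", group,
                lambda network=network, keystones=keystones:
                    stb.keystone_removal_test(network, keystones),
                gdir,
            )
            gsum["keystone_removal"] = krt
            log.write(f"[{group}] keystone removal: dV = {krt['delta_v']:+.4f}")

        if keystones and len(sample_ids) >= 10:
            def _importance(ftable=ftable, keystones=keystones, report=report, group=group):
                rel = nio.relative_abundance(ftable)[keystones]
                y = report.cohesion["np_ratio"].to_numpy()
                if np.all(np.isnan(y)) or np.nanstd(y) == 0:
                    return None
                seed_rf = derive_seed(cfg.seed, "importance", group)
                return drv.keystone_importance(rel, np.nan_to_num(y, nan=np.nanmean(y)),
                                               n_trees=cfg.rf_trees, n_perm=cfg.rf_perm,
                                               seed=seed_rf)

            imp = _run_stage(log, "importance", group, _importance, gdir)
            if imp is not None:
                imp.to_csv(gdir / "keystone_importance.tsv", sep="\t", index_label="taxon")
                gsum["top_keystone"] = str(imp["inc_mse_pct"].idxmax())

        if tree is not None:
            def _assembly(ftable=ftable, group=group):
                seed_a = derive_seed(cfg.seed, "assembly", group)
                zres = asm.bnti(ftable, tree, n_null=cfg.n_null, seed=seed_a)
                rc = asm.rc_bray(ftable, n_null=cfg.rc_null, seed=seed_a + 1)
                part = asm.partition_processes(zres.values, rc)
                return part

            part = _run_stage(log, "assembly", group, _assembly, gdir)
            part.pair_table.to_csv(gdir / "assembly_pairs.tsv", sep="\t", index=False)
            gsum["assembly_fractions"] = {k: float(v) for k, v in part.fractions.items()}
            log.write(f"[{group}] assembly: " + ", ".join(
                f"{k}={v:.3f}" for k, v in part.fractions.items()))

        summary["groups"][group] = gsum

    # ---- cross-group stability comparisons ------------------------------
    comparisons = []
    for i, a in enumerate(group_order):
        for b in group_order[i + 1 :]:
            rob_cmp = stb.compare_stability(robustness_reps[a], robustness_reps[b],
                                            test="paired"
                                            if len(robustness_reps[a]) == len(robustness_reps[b])
                                            else "welch")
            coh_cmp = stb.compare_stability(np_ratio[a].to_numpy(), np_ratio[b].to_numpy(),
                                            test="welch")
            comparisons.append({"group_a": a, "group_b": b,
                                "robustness_t": rob_cmp["t"], "robustness_p": rob_cmp["p"],
                                "np_ratio_t": coh_cmp["t"], "np_ratio_p": coh_cmp["p"]})
    pd.DataFrame(comparisons).to_csv(outdir / "stability_comparisons.tsv",
                                     sep="\t", index=False)
    summary["stability_comparisons"] = comparisons

    # ---- environmental drivers ------------------------------------------
    if env is not None:
        def _drivers():
            y = pd.concat([np_ratio[g] for g in group_order])
            y = y.loc[[s for s in table.sample_ids if s in y.index]]
            common = [s for s in y.index if s in env.index]
            y_c = y.loc[common].to_numpy()
            mask = ~np.isnan(y_c)
            env_c = env.loc[common].iloc[mask]
            y_c = y_c[mask]
            out: dict = {}
            if env_c.shape[1] >= 2 and len(y_c) > env_c.shape[1] + 2 and np.std(y_c) > 0:
                seed_f = derive_seed(cfg.seed, "forward_select")
                selected = drv.forward_select(env_c, y_c, alpha=cfg.forward_alpha,
                                              n_perm=cfg.n_perm, seed=seed_f)
                out["forward_selected"] = selected
            else:
                selected = list(env_c.columns)
            equations = cfg.path_equations or (
                [("stability", selected)] if selected else []
            )
            if equations:
                data = env_c.copy()
                data["stability"] = y_c
                try:
                    res = drv.fit_path_model(equations, data)
                except InvalidInputError as exc:
                    out["path_model"] = {"skipped": str(exc)}
                    return out
                res.coefficients.to_csv(outdir / "path_coefficients.tsv", sep="\t",
                                        index=False)
                res.effects_table().to_csv(outdir / "path_effects.tsv", sep="\t",
                                           index=False)
                out["path_model"] = {
                    "r_squared": {k: float(v) for k, v in res.r_squared.items()},
                    "coefficients": [
                        {"response": r["response"], "predictor": r["predictor"],
                         "coefficient": float(r["coefficient"]), "p": float(r["p"])}
                        for _, r in res.coefficients.iterrows()
                    ],
                }
            return out

        summary["drivers"] = _run_stage(log, "drivers", "pooled samples", _drivers, outdir)
        log.write("drivers: done")

    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True, default=_json_default) + "\n"
    )
    log.dump(outdir / "run.log")
    return summary
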