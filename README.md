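# netstab

Stability analysis of microbial co-occurrence networks, built for
amplicon-style count data (OTU/ZOTU tables) from host-associated or
environmental microbiome surveys — the kind of design where several groups
of communities (host species × environmental condition, treatment ×
control, …) are compared for diversity, assembly mechanism, network
architecture and, above all, *stability*.

The package implements, as one tested pipeline:

* **Diversity & ordination** — Shannon, Simpson, Pielou and bias-corrected
  Chao1 per sample; Bray–Curtis dissimilarity; PCoA; PERMANOVA and ANOSIM
  with seeded permutations.
* **Community assembly null models** — βMNTD, βNTI (tip-shuffle null) and
  Raup–Crick on Bray–Curtis (RC<sub>bray</sub>), partitioned into the five
  Stegen-framework processes: pairs with βNTI > 2 reflect heterogeneous
  selection, βNTI < −2 homogeneous selection; among the |βNTI| ≤ 2 pairs,
  RC > 0.95 is dispersal limitation, RC < −0.95 homogenizing dispersal and
  |RC| ≤ 0.95 drift.
* **Signed co-occurrence networks** — Spearman ρ across samples with
  |ρ| > 0.6 and p < 0.01 edge thresholds (exact permutation p for small
  tie-free samples), after screening taxa to mean relative abundance
  > 0.1% and prevalence strictly above 1/3 of samples; Louvain modules;
  full topology metrics.
* **Stability metrics** —
  * robustness: proportion of taxa surviving random deletion of 50% of
    nodes plus the secondary-extinction cascade in which every survivor's
    abundance-weighted mean interaction strength
    wMIS<sub>i</sub> = Σ<sub>j</sub> b<sub>j</sub>ρ<sub>ij</sub> / Σ<sub>j</sub> b<sub>j</sub>
    is recomputed and nodes with wMIS ≤ 0 drop out, to a fixed point;
  * vulnerability: max<sub>i</sub> (E − E<sub>−i</sub>)/E, with E the
    global efficiency (mean inverse shortest-path length);
  * cohesion: per sample, Σ<sub>i</sub> abundance<sub>i</sub> ×
    connectedness<sub>i</sub>, split into positive and negative parts, and
    the negative:positive (N:P) ratio.
* **Keystone taxa** — Zi–Pi node roles (module hubs Zi ≥ 2.5 & Pi < 0.62,
  network hubs Zi ≥ 2.5 & Pi ≥ 0.62, connectors Zi < 2.5 & Pi ≥ 0.62,
  peripherals otherwise); keystone-removal vulnerability tests; keystone
  importance for a stability response by random-forest %IncMSE with
  rfPermute-style permutation p-values.
* **Environmental drivers** — forward selection of covariates and a
  piecewise standardized linear path model (per-equation OLS on z-scored
  variables) with direct/indirect/total effect decomposition.
* **Synthetic data** — a generator producing study-shaped datasets
  (4 groups × 21 samples, 300 taxa by default) with planted module
  structure, signed edges, phylogeny, assembly regimes and environmental
  path coefficients, so every stage is testable against known truth.

## Worked example

```python
import numpy as np
from netstab import (SynthConfig, simulate_counts, filter_taxa,
                     build_network, detect_modules, zipi,
                     robustness, vulnerability, connectedness, cohesion)

table, truth = simulate_counts(SynthConfig(seed=0))   # 84 samples x 300 taxa
ft = filter_taxa(table)                               # abundance/prevalence screen
net = build_network(ft)                               # |rho| > 0.6, p < 0.01
print(net.n_nodes, net.n_edges)
# 293 11679

part = detect_modules(net, seed=0)
roles = zipi(net, part)
print(part.n_modules, int(roles["keystone"].sum()))
# 3 0

rob = robustness(net, removal_fraction=0.5, n_reps=100, seed=1)
print(round(rob.mean, 3), round(vulnerability(net), 4))
# 0.433 0.0008

coh = cohesion(ft, connectedness(ft, seed=2))
print(round(coh["np_ratio"].mean(), 3))
# 0.607
```

Reading: of the 300 simulated taxa, 293 pass the screen and form a dense
signed network whose Louvain partition recovers the three planted modules
exactly (no node qualifies as a hub or connector in so regular a graph);
after deleting half the nodes at random, on average 43.3% of the original
taxa survive the extinction cascade (the removal alone accounts for 50%,
so some survivors are cascade casualties); no single node carries more
than 0.1% of the network's global efficiency; and negative cohesion runs
at about 0.61× positive cohesion per sample.

A fitted path model prints a statsmodels-style summary:

```python
from netstab import simulate_env, fit_path_model
data = simulate_env(500, {("X", "M"): 0.7, ("M", "Y"): 0.6},
                    noise_sd=np.sqrt(1 - 0.49), seed=3)
print(fit_path_model(["M ~ X", "Y ~ M"], data).summary())
# Standardized path model
# =======================================================
# M  (R^2 = 0.438)
#                  X -> M: beta = +0.662  (p = 0.0000)
# Y  (R^2 = 0.445)
#                  M -> Y: beta = +0.667  (p = 0.0000)
# -------------------------------------------------------
#   X => M: direct +0.662, indirect +0.000, total +0.662
#   X => Y: direct +0.000, indirect +0.441, total +0.441
#   M => Y: direct +0.667, indirect +0.000, total +0.667
```

## Command line

```bash
netstab simulate --outdir data --seed 0            # study-shaped dataset
netstab run --config run.yaml                      # full per-group pipeline
netstab filter data/counts.tsv --out filtered.tsv
netstab network filtered.tsv --outdir net/         # edges.tsv + GraphML (Gephi-readable)
netstab stability filtered.tsv --outdir stab/
```

`netstab run` analyses each group independently (its own filter, its own
network) and writes per-group TSVs, GraphML, a JSON summary and a plain-text
log; reruns with the same config are byte-identical.

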