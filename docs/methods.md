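# Methods

This note documents the statistical machinery in `netstab`, the choices
made where the methods literature leaves the design open, and what the
synthetic-data generator does and does not emulate.

## Count data and taxon screening

The pipeline's substrate is a sample × taxon matrix of non-negative
integer read counts (denoised amplicon OTUs/ZOTUs). All analyses work on
relative abundances within a sample; no rarefaction is performed. Before
network construction taxa are screened: a taxon is retained when its
across-sample **mean** relative abundance exceeds 0.1% *and* it occurs in
strictly more than 1/3 of the samples. Two conventions are deliberate
here: "more than 1/3" is a strict inequality on the fraction of samples
(2 of 6 samples fails, 3 of 6 passes), and the abundance criterion is
applied to the mean rather than the maximum (a `abundance_statistic="max"`
flag switches the convention). Screening is applied per analysis group, so
each group's network is built from its own samples.

## Diversity

Shannon H = −Σ p ln p, Gini–Simpson 1 − Σ p², Pielou J = H/ln S (undefined,
reported as missing, for single-taxon samples) and the **bias-corrected**
Chao1, S + F₁(F₁−1)/(2(F₂+1)), chosen so samples without doubletons remain
defined. Group contrasts of alpha indices use Welch's t-test by default
(`equal_var=True` for Student's).

Bray–Curtis dissimilarity is computed on relative abundances and is a
semimetric: the triangle inequality is not guaranteed and nothing in the
package assumes it. PCoA is classical (Torgerson) scaling: Gower
double-centering followed by an eigendecomposition. Negative eigenvalues —
expected for non-Euclidean dissimilarities — are retained in the report
but excluded from the proportion-explained denominator, matching the
common R behaviour; a Cailliez-type correction is intentionally not
applied.

PERMANOVA uses Anderson's decomposition of squared distances
(R² = SS_between/SS_total, pseudo-F on the usual degrees of freedom);
ANOSIM uses Clarke's R = (r̄_B − r̄_W)/(M/2) with M = n(n−1)/2, the divisor
that makes perfectly separated groups reach exactly R = 1. Both tests
permute group labels with an explicit seeded generator and report
p = (1 + #{perm ≥ obs})/(1 + n_perm), so the smallest attainable p is
1/(n_perm+1); the default is 999 permutations. With small balanced
designs the permutation distribution has ties at the maximum whenever a
permutation reproduces the observed partition, so the floor is reached
only when group sizes make that probability negligible.

## Community assembly null models

βMNTD between communities k and l is the abundance-weighted mean distance
from each taxon to its nearest relative in the paired community,
0.5·[Σ_i f_ik·min_{j∈l} d(i,j) + Σ_j f_jl·min_{i∈k} d(j,i)], with f the
relative abundances (or 1/richness when unweighted) and d patristic
distances. A taxon shared by both communities is its own nearest relative
(distance 0). βNTI is the z-score of observed βMNTD against a null that
shuffles taxon labels across all tree tips — equivalently, a joint
row/column permutation of the patristic matrix — preserving richness and
abundances, the same null as picante's "taxa.labels". Default 999
iterations (minimum 99 enforced); pairs whose null standard deviation is
zero are flagged degenerate and assigned βNTI = 0 rather than dropped.

RC_bray re-assembles each sample probabilistically: its observed richness
is drawn without replacement with probability proportional to occupancy,
and its observed total abundance is distributed over the drawn taxa
proportionally to pool-wide relative abundance. One null community per
sample per iteration serves every pair in that iteration. RC is the rank
of the observed Bray–Curtis value in the null distribution, rescaled to
[−1, 1] with ties counted half.

Pairs are classified: βNTI > 2 heterogeneous selection; βNTI < −2
homogeneous selection; otherwise RC > 0.95 dispersal limitation,
RC < −0.95 homogenizing dispersal, |RC| ≤ 0.95 drift. The ±2/±0.95
thresholds are the standard two-stage convention; the five fractions
always sum to 1.

## Co-occurrence networks

Edges are Spearman correlations across samples (mid-ranked ties),
retained when |ρ| strictly exceeds 0.6 **and** the two-sided p is
strictly below 0.01. For n ≤ 9 samples without ties the p-value is exact,
computed from the full n! permutation distribution of ρ (cached per n);
otherwise the t approximation is used. A perfectly monotone pair over 4
samples has exact p = 2/4! = 1/12 and therefore never forms an edge — the
sample-size floor is real, not an artifact of the approximation. Multiple
testing correction is off by default (the thresholds are used as given);
Benjamini–Hochberg is available by flag. Constant taxa have undefined
correlations: their pairs are skipped with a warning and they remain in
the node set as isolated nodes, as does any screened taxon without a
qualifying partner.

Module detection is Louvain greedy modularity maximization on unweighted
edge presence with a fixed seed (the de facto standard of interactive
network tools); modularity Q is Newman's. Topology metrics: mean degree
2E/N, density 2E/(N(N−1)), unweighted average path length and diameter on
the largest connected component, mean local clustering, and mean
betweenness/closeness centrality with their standard normalizations.

Node roles use within-module degree z-score Zi (0 when the module's
within-degree spread is zero) and participation coefficient
Pi = 1 − Σ_s (k_is/k_i)² (0 for isolated nodes), both on unsigned edge
presence. Thresholds: module hubs Zi ≥ 2.5 & Pi < 0.62; network hubs
Zi ≥ 2.5 & Pi ≥ 0.62; connectors Zi < 2.5 & Pi ≥ 0.62; all others
peripheral. Non-peripheral nodes form the candidate keystone set.

## Stability

**Robustness.** Each replicate deletes ⌊0.5·N⌋ nodes uniformly at random,
then iterates the extinction rule to a fixed point: every survivor's
abundance-weighted mean interaction strength over surviving neighbours,
wMIS_i = Σ_j b_j ρ_ij / Σ_j b_j, is recomputed and all nodes with
wMIS ≤ 0 are removed simultaneously. Survivors with no remaining
neighbours have wMIS = 0 and are removed by the ≤ 0 rule — an isolated
taxon has lost the interactions the metric credits with persistence. The
replicate value is survivors/N; the default is 100 replicates, reporting
mean, sd and the full vector. Both the threshold and the simultaneous
update are the deterministic reading of the cascade; they are exposed in
the function signature rather than hard-coded beliefs.

**Vulnerability.** Global efficiency E is the mean of 1/d(i,j) over
ordered node pairs with hop-count shortest paths, disconnected pairs
contributing 0. Vulnerability is max_i (E − E_{−i})/E, where E_{−i} is
the efficiency of the graph with node i deleted, normalized over the
remaining N−1 nodes; V = 0 when E = 0. Note that under this definition
removing a node from a cycle C_n with n ≥ 5 *does* change efficiency
(deleting a C₅ node leaves P₄, V ≈ 0.037); only highly redundant graphs
such as cliques, or C₄, have V = 0. The keystone-removal test reports
vulnerability before and after deleting the whole keystone set, with
ΔV = V_after − V_before signed (removing a star's centre makes the
remainder edgeless: V_after = 0, ΔV = −1 — a drop in *measurable*
efficiency contribution, not an increase in stability, which is why both
endpoints are reported and not just the difference).

**Cohesion.** Pairwise Pearson correlations on relative abundances are
null-corrected by subtracting the mean correlation over 200 iterations of
independent within-taxon permutations ("taxa shuffle"); an uncorrected
"observed" mode exists for sensitivity analysis. Each taxon's positive
(negative) connectedness is the mean of its positive (negative) corrected
correlations. Per sample, cohesion_pos = Σ b_i·pos_i ≥ 0 and
cohesion_neg = Σ b_i·neg_i ≤ 0 over all m taxa of the community, and the
N:P ratio is |cohesion_neg|/cohesion_pos (missing when positive cohesion
is zero). Group comparisons of stability vectors use Welch's or paired
t-tests; identical paired vectors return t = 0, p = 1 by convention.

## Drivers

**Keystone importance** is %IncMSE from a bagged regression forest built
in-package over CART trees (mtry = p/3, 500 trees by default): per tree,
the out-of-bag MSE is compared before and after permuting one column, and
%IncMSE is the mean relative increase in percent. Significance follows
the rfPermute recipe: the whole forest is refit on permuted responses
(default 100 times) and p = (1 + #{null ≥ obs})/(1 + n_perm). The
per-sample stability response defaults to N:P cohesion — robustness and
vulnerability are per-network quantities and cannot serve as a per-sample
regressand; any per-sample metric can be substituted.

**Forward selection** greedily adds the environmental variable with the
largest adjusted-R² gain, accepting it only if a permutation test of that
gain (permuting the candidate's values, 999 draws) gives p ≤ 0.05 and
adjusted R² increased; collinear candidates are skipped with a warning
and ties break by column order.

**Path model.** The piecewise structural equation model is reduced to its
estimable core: each equation is ordinary least squares on z-scored
variables, so coefficients are standardized path weights with t-test
p-values and per-equation R². Direct effects are edge coefficients;
indirect effects sum coefficient products over all directed paths
(equivalently, entries of (I−B)⁻¹−I for the nilpotent weight matrix B);
total = direct + indirect. Fisher's C d-separation test is out of scope —
the model evaluates the paths it is given, it does not test the DAG.

## Synthetic data

The generator emulates the structure of a processed multi-group amplicon
survey — by default 4 groups × 21 samples and 300 taxa, the emulated
study design — not any particular biological system:

* **Counts.** A latent multivariate normal with block covariance
  (ρ_within = 0.8 inside each of 3 modules, ρ_between = 0 across; a
  fraction of taxa per module get negated loadings so ~30% of
  within-module pairs are sign-discordant) is exponentiated to log-normal
  intensities around a log-normal abundance spectrum (sd 0.5) and closed
  compositionally by one multinomial draw per sample at depth 50,000.
  The multinomial closure matches amplicon data and *matters*: dividing by
  the fluctuating total attenuates within-module rank correlations
  (latent Spearman ≈ 0.77 → observed ≈ 0.7) and biases between-module
  correlations negative. The defaults were calibrated once, at design
  time, so that ≥ 80% of true within-module pairs among screened taxa
  pass the |ρ| > 0.6, p < 0.01 edge criteria at 84 samples — the
  generator must be strong enough to feed the network stage, and sign
  balance plus a flat-ish abundance spectrum keep the closure distortion
  in check. Non-PSD covariances are repaired by clipping eigenvalues at
  1e-10 and renormalizing to unit diagonal (deterministic and cheap); the
  block construction itself is always PSD.
* **Phylogeny.** Pure-birth (Yule) trees with unit birth rate, rescaled
  to height 1 — simple, ultrametric, and sufficient for βMNTD-style
  tests. Tips are labelled in birth order; identical seeds give
  byte-identical Newick.
* **Assembly regimes.** *Drift*: multinomial draws from a fixed regional
  pool. *Selection*: a Brownian trait on the tree filters the pool by a
  Gaussian kernel around each community's optimum; communities alternate
  between two optima one trait-sd apart. *Dispersal limitation*:
  phylogeny-independent contiguous windows of a shuffled pool; with
  evenly dividing community counts the windows are disjoint.
* **Environment.** A linear-Gaussian DAG with user-specified standardized
  path weights; all columns z-scored on return.

What the generator does **not** emulate: real zero-inflation and
overdispersion beyond log-normal×multinomial, phylogenetic signal in the
*abundances* (modules are independent of the tree), sequencing batch
effects, or any group-level mean shift (the four groups are exchangeable,
so between-group tests are calibrated under the null rather than
reproducing any particular effect size). Passing tests therefore
demonstrate correctness and calibration of the machinery, not performance
on real dysbiosis data.

## Determinism and problem sizes

No stage consumes global randomness: every stage seed is derived as
crc32(master_seed:stage:group) < 2³¹, so a pipeline rerun with one master
seed is byte-identical. The test suite exercises the full study shape
(4 × 21 × 300) for the determinism check with reduced iteration counts
(99 βNTI nulls, 49 RC nulls, 20 robustness replicates, 30-tree forests),
and uses 20 communities × 100 taxa with 999 nulls for the neutral-regime
βNTI calibration; these sizes are the package's chosen test design and
are stated here so results can be reproduced exactly.

## Known limitations

* Spearman-threshold networks ignore compositionality; SparCC/SpiecEasi
  style inference is deliberately out of scope, and the generator's
  closure bias is part of what the analysis sees.
* The robustness cascade's wMIS ≤ 0 rule removes isolated survivors,
  so robustness can fall below 1 − removal fraction even in all-positive
  networks with sparse structure.
* p-value resolution is bounded by the permutation count; permutation
  tests on tiny balanced designs cannot reach the nominal floor.
* The path model assumes linearity and no latent confounding; it
  decomposes effects along the supplied DAG without testing it.
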