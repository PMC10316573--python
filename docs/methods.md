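# Methods

## Scope and data model

The pipeline operates on a samples × taxa matrix of non-negative relative
abundances (`AbundanceTable`), optionally annotated with GTDB-style
seven-rank lineages and per-sample group labels, plus a samples × traits
matrix of continuous phenotypes (`TraitTable`) in which missing values are
allowed. Orientation of input TSVs is always explicit (default
rows-are-samples); rows that do not sum to 1 are treated as counts and
normalized with a logged notice. Prevalence filtering ("abundance
> a in strictly more than f of samples") is available but off by default,
since co-occurrence analysis is often run on the full taxon panel.

## Correlation networks

Spearman ρ is the Pearson correlation of midranks (average ranks over tie
groups), computed vectorised over all taxon pairs. Two-sided P-values use
the t approximation with n − 2 degrees of freedom; this is the standard
choice at feeding-trial group sizes (n = 16), where exact permutation
enumeration is infeasible. A seeded permutation estimate (independent
column permutations, add-one correction) is available for small panels.
Taxa that are constant across samples are retained with ρ = 0, P = 1 and a
logged flag — sparse MAG tables routinely contain them, and erroring would
be hostile.

Benjamini–Hochberg adjustment is applied once per group over the strictly
upper triangle of the P matrix, then mirrored. The edge rule is strict on
both sides: |ρ| > 0.7 *and* selected P < 0.05. Because the source
methodology names BH correction before its P threshold, the adjusted P is
screened by default; a raw-P mode is provided because published network
papers are frequently ambiguous on this point, and neither choice is
asserted as "the" published one. Taxa with no surviving edge are dropped
from the node set by default, which is why node counts fall below taxon
counts.

## Topology, modularity, nulls

All topology is computed on the unweighted, sign-collapsed simple graph;
signs survive only as edge attributes and in the positive-edge fraction.
ACC is the mean of per-node clustering 2T/(k(k−1)) (0 for k < 2). APL
averages BFS shortest paths over ordered reachable pairs excluding
self-pairs — not over the giant component — so it stays defined for the
fragmented, high-module-count graphs that strict FDR screening produces;
the diameter is the largest finite distance. Unreachable-pair exclusion is
reported in the run summary. Both E/N and 2E/N are reported for "edges per
node" because the literature uses the phrase for either.

Modularity Q = Σ_c [e_c/m − (d_c/2m)²] is implemented directly from the
formula (and cross-checked against networkx in the tests). Module
detection is seeded Louvain — the algorithm behind Gephi's module
colouring — with greedy agglomerative merging as an alternative; detected
module labels are canonicalised (largest module first) so runs are
reproducible. Singleton components count as modules. A partition is
labelled modular when Q > 0.4, the conventional cut-off.

The default null model is degree-preserving Maslov–Sneppen double-edge
swapping (10·m accepted swaps per replicate), the stricter and standard
ecological-network null; uniform G(n, m) is available as an option since
"randomized network" is ambiguous in much of the literature. The ensemble
summary reports per-metric null mean, sd, and z-score, flags a degenerate
null sd (z undefined) rather than dividing by zero, and calls a graph
"modular/small-world-like" when observed ACC and Q both exceed their null
means. Default replicate count is 100 in the pipeline (the CLI exposes
it); the validation suite uses 30–50 replicates, which is ample for
z-scores in the tens.

## Node roles

Zi for node i in module s is (k_is − mean_s)/sd_s with k_is the links from
i into its own module and moments taken over the members of s (population
sd; sd = 0 → Zi = 0). Pi = 1 − Σ_s (k_is/k_i)², 0 for isolated nodes.
These formulas are stated explicitly because role-analysis papers often
cite them without printing them: Zi uses only within-module links, Pi uses
total degree. Default cuts follow the Guimerà–Amaral convention adopted
throughout ecological network analysis — zi_cut 2.5, pi_cut 0.62 — with
boundary ties assigned to the hub/connector side for determinism. Both
cuts are exposed in the API and CLI since upstream studies rarely print
theirs.

A geometric consequence worth noting: a node whose links touch only two
modules has Pi ≤ 0.5 and can never clear the 0.62 connector cut. The
ring-of-cliques benchmark therefore joins cliques with dedicated bridge
nodes adjacent to one member of each of *three* consecutive cliques
(Pi = 2/3); a bridge-edge variant (direct clique-to-clique edges, endpoint
Pi = 0.32) is kept for testing that participation is merely positive.

## Community metrics and associations

Shannon entropy is in nats; Simpson is 1 − Σp², InvSimpson its reciprocal.
Bray–Curtis uses 1 − 2Σmin/Σ(a+b) via scipy. The family indicator ratio
aggregates lineages at family rank; a zero denominator yields a flagged
infinity unless a pseudocount (added to both terms) is requested — the
handling is a config option because source studies rarely state theirs.

Differential abundance is the two-sided Wilcoxon rank-sum test per taxon
with BH over all tested taxa. The exact null distribution is used when the
combined n ≤ 20 without ties, otherwise the tie-corrected normal
approximation with continuity correction; an all-constant taxon gets P = 1
by convention. LDA effect-size scoring in the LEfSe style is a published
external tool and deliberately out of scope.

Trait screening reuses Spearman machinery over the taxon × trait rectangle
and trait × trait triangle, corrected as two separate BH families
(mirroring the two panels of a typical correlation figure), with the
strict double criterion |ρ| > 0.35 and selected P < 0.05. Missing trait
values are handled pairwise-complete with per-pair n reported; pairs with
fewer than 4 complete observations are flagged untestable, never silently
dropped.

## Synthetic data

The generator is a latent-Gaussian copula with log-normal marginals.
Block b has one N(0,1) factor per sample; a member taxon's latent score is
√c·factor + √(1−c)·noise with c = `latent_corr`, so the within-block
latent correlation is exactly c and the planted-correlation strength is a
single interpretable dial (a Dirichlet scheme would not give that).
Keystone taxa load on the normalised sum of several block factors. Latent
scores are shifted by per-taxon N(μ, σ) log-baselines, perturbed by
per-sample multiplicative noise (log-scale sd `noise_sigma`, default 0.1),
exponentiated, and closed to sum 1.

Default spec: 2 groups × 16 samples, 200 taxa (desk scale — the taxon
count is a parameter), five blocks of 12/10/10/8/8 taxa, latent_corr 0.85,
three keystone bridges, and seven traits (SCFAs, ghrelin, IGF-1, body
weight) linked to block taxa with slope 0.6–1 and noise sd half the signal
sd, plus one pure-noise trait. Trait noise sds are expressed relative to
the sd of the trait's signal component: relative abundances are O(1/200),
so absolute noise parameters would be meaningless across panel sizes.

What the generator does *not* emulate: sequencing noise and zero
inflation, phylogenetic correlation, dose–response group effects (groups
are exchangeable by construction, which is exactly what the
false-positive-control experiments need), and taxon-specific dispersion.
Passing tests therefore demonstrate correctness of the inference chain on
data with known structure, not robustness to every pathology of real
metagenomic tables. Closure does induce the mild compositional
negative-correlation artifact, deliberately.

## Validation strategy and problem sizes

Exact quantities are pinned to analytic oracles (two disjoint K4 cliques:
Q = 1/2; C5: APL = 1.5; hand-enumerated clustering of K4 minus an edge:
ACC = 5/6; Zi = 2 / Pi = 1/2 fixtures; exact Wilcoxon on fully separated
3-vs-3: P = 0.1 by enumerating all 20 assignments). Statistical machinery
is checked against independent re-implementations (hand-written
midrank-Pearson for Spearman, a brute-force step-up scan and statsmodels
for BH). Null models are checked against their contracts (exact degree
multisets; G(n,m) mean clustering = edge density). End-to-end recovery
uses 5 blocks × 10 taxa with latent_corr 0.9 at 100 samples plus 50
independent taxa — at these settings within-block Spearman ≈ 0.88, far
above the 0.7 edge cut, so near-total edge recall and ARI ≈ 1 are the
correct expectation, while independent taxa must stay edge-free; the
false-positive control uses the study-scale 16 samples per group on 200
independent taxa. These sizes keep the whole suite around a minute on one
CPU while leaving wide statistical margins.

## Reproducibility

Every stochastic stage draws from a generator seeded deterministically
from one integer (per-stage sub-seeds via `numpy.random.SeedSequence`);
Louvain, rewiring, and the generator are all seeded. Reports are JSON with
sorted keys and no timestamps, so identical config + seed produce
byte-identical files; the report validates against a versioned schema
shipped with the package.

## Known limitations

- Compositionality is not corrected for (no SparCC/SPIEC-EASI-style
  inference); at a few hundred taxa the closure artifact is small, but
  strongly dominated compositions would bias ρ downward.
- The t approximation for Spearman P is approximate under heavy ties at
  small n; the permutation option exists for that case.
- APL/diameter are descriptive on fragmented graphs; comparisons across
  networks with very different component structure should lean on the
  null-model z-scores instead.
- Role classification inherits the arbitrariness of the Zi/Pi cuts; the
  defaults are conventional, not optimal.
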