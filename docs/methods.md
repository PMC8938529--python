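# Methods

This note records the models, estimators and numerical choices behind
`concordex`, in the order the pipeline runs them, together with what the
synthetic data do and do not emulate.

## Synthetic data generator

The generator draws two bulk RNA-seq experiments with a shared gene space.
Experiment A crosses genotype (WT, hMet) with treatment (VEH, CORT);
experiment B crosses housing (SH, EE) with defeat outcome (SUS, RES); each
of the four groups per experiment has `n_per_group = 6` replicates.

**Count model.** Gene g in sample s has log₂ mean
`b_g + l_g · f_{m(g),s} + shift_gs`, where `b_g ~ N(5, 1.5²)` is a
baseline abundance (typical bulk depth, mean count ≈ 50), `l_g` is a
module loading drawn once per gene and reused in both experiments, and
`f_{m,s} ~ N(0,1)` is the latent factor of gene g's module in sample s.
Counts are negative binomial with that mean scaled by a lognormal
library-size factor (`sd = 0.25` on the log scale) and a dispersion of 0.2
shared by all genes, the overdispersion scale typical of bulk tissue
replicates.

**Planted structure.** Ten modules of 50 genes are scattered over 2000
genes; module genes load positively (`l_g ~ U(0.35, 0.7)`) on their
factor, producing within-module Pearson correlations around 0.3–0.4 on
log-CPM against a ~0 background. Two modules carry planted differential
expression of +0.6 log₂ units (fold change ≈ 1.52): the susceptibility
module in CORT-treated groups of both genotypes and in SH-SUS; the
resilience module in hMet-VEH and EE-SUS. This reproduces the concordance
pattern the pipeline is meant to detect: one module shared by
susceptibility-like groups across models, one by resilience-like groups.

**Factor centering.** Latent factors are centered within each experimental
group. An uncentered factor's group-mean noise (≈ `l·sqrt(2/6)` ≈ 0.3–0.4
log₂ units) moves an entire module coherently in any given draw, which at
six replicates is the same order as the planted shift — ground truth would
then be unidentifiable and every seed a coin flip. Centering makes the
expected group contrast exactly the planted shift while leaving
within-group (co-expression) variance untouched. One side effect is that
the moderated t is mildly conservative on module genes: their within-group
variance still contains the factor term even though the contrast estimate
does not.

**Loading range.** The loading is the one free dial that trades
co-expression strength against DE power, because the NB dispersion already
fixes a per-sample noise floor of ≈ 0.65 log₂ units: with per-sample sd
`sqrt(l² + 0.42)`, stronger loadings make modules easier to cluster but
bury the 0.6-unit shift. `U(0.35, 0.7)` is the middle of that trade and
was fixed before the acceptance tests were written.

**Behavior.** Each behavioral variable is normal with a group-specific
mean; susceptible-like groups (CORT-treated, defeat-susceptible) are
shifted by one control SD in the emotionality-increasing direction of that
variable (direction map: less time in light, fewer/shorter grooming bouts,
longer latency to light and to groom, less SI-zone time, lower SI ratio =
more emotionality). The SI ratio is drawn from truncated normals on the
proper side of 1 so that ratio-based classification reproduces the group
labels. Ten animals per group, as in the behavioral cohorts the design
mimics.

**What the generator does not emulate:** batch effects, sample pooling
(the CORT arm of the original design pooled RNA from two animals per
replicate; replicates here are independent animals), gene-length effects,
count compositionality beyond the shared library-size denominator, and
any non-Gaussian behavioral distributions. Passing tests therefore show
that the estimators recover planted structure of realistic effect size
under clean NB noise — not that they are robust to confounding.

## Differential expression

Counts become `log2((count + 0.5) / (libsize + 1) * 1e6)`. The fixed prior
count stabilizes zeros; its cost is a small depth-dependence (doubling
depth shifts a count-10 gene by 0.035 log₂ units, vanishing as 1/count).
The moderated t pools the two group variances (d_g = n₁+n₂−2), estimates
the prior (d₀, s₀²) from the moments of log s²_g (Fisher-z moments of a
scaled χ²; the trigamma equation is inverted by Newton iteration), and
tests t = FC/(s̃·c) on d₀+d_g df. `d0=0` and `d0=inf` overrides expose the
no-shrinkage and complete-shrinkage limits used by the tests. Voom-style
precision weights are accepted but off by default: at the simulated depths
the weights are nearly flat, and the unweighted path is fully specified.
DEGs require uncorrected p < 0.05 **and** natural-scale fold change > 1.3,
both strict; ranking scores are −log₁₀(p)·sign(log₂FC) with lexicographic
tie-breaks.

## Stratified RRHO

Both lists must rank the same background. Genes with score > 0 form the up
stratum; scores of exactly 0 (only possible at p = 1) fall to the down
stratum so the split is deterministic. Quadrant UU scans the top-i of list
1 against the top-j of list 2 (i, j within the up strata), DD scans from
the bottoms, UD/DU mix one top with one bottom; every cell stores
−log₁₀ of the raw upper-tail hypergeometric p over the full background N.
The default step is ceil(sqrt(N)) — ≈ 45 for a 2000-gene background,
≈ 131 for a transcriptome — keeping grids near 150² cells; thresholds
always include the stratum end so no gene is unreachable. A BH/BY-adjusted
grid (joint across all cells of all quadrants) can be stored alongside the
raw one; peaks are always read from the raw grid, ties resolved toward the
smallest row then column threshold. Peak gene sets are the overlap at the
peak cell and inherit the quadrant's direction strata by construction.

## Consensus network and modules

Signed adjacency `((1+cor)/2)^β` with Pearson correlation; signed networks
preserve the up/down concordance the analysis interprets. β is the
smallest candidate (1–20) whose signed scale-free fit R² reaches 0.8 per
dataset, with an argmax fallback under a warning; the pipeline uses the
max over the two datasets so the thresholding suits both. TOM follows the
standard shared-neighbor formula with unit diagonal. The second TOM is
multiplicatively rescaled so its 0.95 off-diagonal quantile matches the
first's, then the consensus is the element-wise minimum — a pair is
connected in the consensus only if connected in both experiments.

Clustering is average linkage on 1 − TOM. Because high β compresses all
merge heights into a narrow band near 1, the cut is placed at a fraction
(default 0.995) of the dendrogram height *range*, and applied top-down:
every branch joining at or above the cut is split recursively, branches
joining below it become modules, and branches that cannot produce
`min_size` genes fall to background. Three refinements follow:

* **kME reassignment** (the PAM stage of dynamic tree cutting): each gene
  moves to the module with its highest mean-over-datasets eigengene
  correlation when that exceeds 0.35, else to background; iterated to a
  fixed point (≤ 5 rounds).
* **Residual re-seeding**: the background genes are re-cut up to twice —
  a single pass over a noisy consensus dendrogram reliably loses one or
  two true modules, which the residual tree then isolates cleanly.
* **Eigengene merging**: modules whose consensus eigengene dissimilarity
  (max over datasets of 1 − cor) falls below 0.25 are merged iteratively.

Seeding accepts 20-gene fragments so true modules are not lost, but the
final partition drops modules below 30 genes: clusters that fail to grow
during kME refinement are overwhelmingly correlation-noise artifacts
(an aggressive search over ~1500 background genes at 24 samples per
dataset finds many mutually correlated 20-gene sets by chance), and they
both dilute the enrichment family and occasionally reach significance
through their coherent sampling noise. A permutation-calibrated validator
(`null_coherence_floor`) that re-runs detection on sample-permuted data is
available in the library but is not part of the default path: the
artifact coherence ceiling lands inside the real modules' coherence range
once those carry ~30% background contamination, so pruning by it costs
recall.

Eigengenes are first principal components of the standardized module
submatrix, unit-norm, sign-oriented along the module mean profile; kME is
the Pearson correlation of each gene with each eigengene, reported per
dataset and combined as the plain mean (the combination rule is not fixed
by convention; the mean is symmetric and keeps kME in [−1, 1]).

## Module statistics

Every module × DEG-set pair gets a one-sided Fisher exact test (upper
hypergeometric tail) over the network background; DEG genes missing from
the background are dropped with a logged count. BH adjustment is applied
jointly across the whole module × set family — the conservative scoping
when a single FDR threshold is quoted without a family. The relevance
score is the mean −log₁₀ adjusted p over the eight directional sets (a
raw-p variant sits behind a flag); a module is *key* when significantly
enriched (adjusted p < 0.05) in at least one set from each experiment.
Hubs are members with consensus kME above the module mean plus one sample
(n−1) standard deviation, strict inequality — a module of identical kMEs
has no hubs, and a singleton module has no defined spread and errors.
Ranking by intramodular connectivity (summed TOM) is available via
`metric="kin"` since "most connected" admits both readings.

## Behavioral scores

Directional z per variable against the comparison's control group;
emotionality = mean z within each behavioral test, then the equally
weighted mean across tests. The normalized behavioral score first shifts
all composite z by the cohort minimum ("normalized to the lowest z",
read as subtraction; a divide variant that additionally rescales by the
minimum's magnitude sits behind a flag — pure division is degenerate
because control z averages zero by construction), sets ā to the mean
shifted control z, and reports 1 − z/ā: the cohort's least-emotional
animal scores exactly 1, an animal at the control mean exactly 0, and the
score is strictly decreasing in emotionality. ā = 0 (constant controls)
is an error. SI ratio exactly 1 classifies as SUS — resilience is defined
strictly as ratio > 1, so the boundary closes conservatively. Cohort
percentages are reported at full precision and rounded to integers for
display; association between phenotype and housing uses the two-sided
Fisher exact test.

## Numerical and reproducibility choices

All randomness flows from `numpy.random.default_rng` seeded by the run
config; re-running a config reproduces artifacts byte-for-byte, and every
artifact header embeds a SHA-256 hash of the config (excluding the output
path). Hypergeometric tails use `scipy.stats.hypergeom.sf`; the test
suite checks them against exact rational-arithmetic enumeration. p-values
are floored at the smallest positive double before −log₁₀. Zero-variance
genes are removed before network construction with a logged count. Module
labels are always reassigned in decreasing size order so partitions are
comparable across runs.

## Known limitations

Per-gene DEG power at the simulated conditions is ~0.2, so module/DEG-set
overlaps are Binomial(50, ~0.2) draws: in roughly one seed in five a
critical single-set enrichment lands at k ≤ 5–6 and misses the joint-BH
0.05 line, costing one key flag (or, more rarely, a noise module gains
one). The acceptance-style concordance check therefore evaluates five
seeds and requires four successes. The "top-down dynamic tree cut" here
is the recursive height-threshold variant, not the full hybrid algorithm;
TOM calibration is multiplicative at a single quantile rather than full
quantile normalization; and the DE layer fits two-group contrasts only —
no factorial model, covariate adjustment or TMM normalization.
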