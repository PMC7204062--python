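# Methods

This note documents the models, estimators, numerical choices, and the
synthetic-data design behind `rindqtl`, and what the passing tests do and do
not establish about real field data.

## Synthetic RIL populations

The generator emulates a biparental maize RIL population phenotyped for rind
penetrometer resistance (RPR, kg/mm²) at seven stages (V10, DTS, AS10–AS50)
in several environments with replicates.

**Meiosis.** Crossovers are a Poisson process on the centimorgan scale with
no interference (Haldane), so the per-meiosis recombination fraction across a
gap of `d` cM is `r = (1 − e^(−2d/100))/2`. Selfing to fixation inflates the
observed recombinant fraction to `R = 2r/(1+2r)`. The default "F∞" mode
applies this expansion directly as a two-state Markov chain along each
chromosome — exact for adjacent-pair probabilities and fully vectorised; an
explicit generation-by-generation selfing mode (tracking both homologs
through meioses, residual heterozygotes coded 1) exists for validating the
shortcut, and the two agree on realized recombinant fractions within sampling
error. Interference is deliberately ignored in *simulation*; the Kosambi
function, which allows for interference, is used only for map *estimation*,
mirroring common simulator practice. Crossover positions and the initial
parental state per chromosome are retained as ground truth, so the genotype
at any map position (e.g. an off-marker QTL) can be evaluated exactly.

**Segregation distortion** is produced by rejection resampling: lines are
kept with probability proportional to the target transmission ratio of their
allele at the distorted locus. This hits the configured parent-1 frequency in
expectation while leaving the linkage structure around the locus intact.

**Phenotypes** follow the trial model
`y_ijk = μ + g_i + e_j + ge_ij + r_k(j) + ε_ijk`. The genetic value `g_i` per
stage is the sum of configured QTL contributions (dosage ±1 times a per-stage
additive effect) and a polygenic value drawn with a configurable stage
correlation matrix (default: post-silking stages pairwise 0.9, DTS 0.75 to
them, V10 only 0.25–0.30 — the vegetative stage is a deliberate outgroup).
When per-stage heritability targets are given, the residual SD is solved from
the entry-mean identity `H² = σ²_g/(σ²_g + σ²_ge/e + σ²_ε/(re))` using the
*realized* genetic variance, so estimated heritabilities recover the targets.
Default scale: grand mean 4.0 kg/mm², QTL effects of 0.1–0.3 kg/mm², stage
heritabilities 0.45–0.85 with V10 lowest. The replicate term `r_k(j)` has its
own SD (default 0: replicate effects are usually negligible relative to plot
error, and a zero default makes the no-noise limit exact).

What the generator does **not** model: array hybridization noise beyond a
flat error rate, epistasis, spatial field trends, selection during line
development, or within-line measurement replication beyond the replicate
term. Passing recovery tests therefore show the estimators are correct under
the stated generative model, not that field data meet its assumptions.

## Phenotype statistics

Variance components come from the expected-mean-square identities of the
balanced two-way design with replicates nested in environments
(`σ̂²_ε = MSE`, `σ̂²_ge = (MS_GE − MSE)/r`, `σ̂²_g = (MS_G − MS_GE)/(re)`);
negative moment estimates are truncated to zero and flagged. Unbalanced
tables are rejected with the missing cells named. With a single environment
the GE term is dropped.

BLUEs treat genotype as fixed and GE and replicate-within-environment as
random in a dense GLS with the moment (or, optionally, REML) components.
The environment main effect enters as a **sum-to-zero fixed contrast** rather
than a random term: with only 2–3 environments its variance is not estimable
from moments on unbalanced data, and the fixed contrast yields identical
BLUEs under balance (where they collapse to line means) while keeping the
unbalanced GLS well posed.

Genetic correlations use method-of-moments mean cross-products — the
multivariate analog of the EMS rules, `cov_g = (MCP_G − MCP_GE)/(re)` — with
`r_g` truncated to [−1, 1]. A REML refinement is not implemented; the moment
estimator was chosen because it admits an exact closed-form oracle and is
unbiased on simulation (mean estimate 0.80 ± 0.05 at a generative 0.8).

Stage clustering standardizes BLUE columns to zero mean and unit
*population* (1/n) variance — this affects only the distance scale, not the
topology — and applies complete-linkage agglomerative clustering to the
Euclidean distances; the linkage rule is recorded in the output metadata and
the tree is exported as a nested-list JSON and a Newick string.

## Marker QC, bins, and the linkage map

QC removes markers with missing rate > 0.20 **or** MAF < 0.05, both strict
inequalities so boundary markers survive; segregation χ² (1:1, df 1,
heterozygotes excluded) removes markers with P < 0.05. Both filters are
idempotent.

Bin calling slides a window (default 15 SNPs, step 1) along each line's
physically ordered markers, votes a window genotype when the majority
fraction ≥ 0.7, places breakpoints at physical midpoints between the centers
of flanking informative windows where the call changes, cuts population bins
at the union of breakpoints, and collapses adjacent bins with identical
population columns. The defaults are recorded in every run manifest. On
simulation with 1% genotyping error, bin genotypes match the error-free truth
at ≥ 99% of entries.

Linkage maps fix marker order by physical position (de-novo ordering is out
of scope). Adjacent-pair recombinant fractions R (mismatch frequency among
doubly homozygous lines) are converted to per-meiosis fractions with the
inverse RIL expansion `r = R/(2(1−R))` (toggleable), capped at 0.4999, then
to cM with Kosambi `d = 25·ln((1+2r)/(1−2r))`. Pairs with R ≥ 0.5 are capped
with a warning. A per-chromosome collinearity report (Spearman correlation of
bp vs cM orders) is emitted as a pipeline self-check; with physical ordering
it is 1 by construction up to ties.

## Composite interval mapping

Genotype probabilities on a 1-cM pseudo-marker grid come from two-state
Markov interpolation using RIL-expanded Haldane fractions; at observed
non-missing markers the observed class has probability 1, and missing flanks
fall back to the nearest informative marker. The scan is regression-based
(Haley–Knott) rather than an EM mixture so it has a closed-form oracle:
the expected-dosage regression at each position, plus forward-selected marker
cofactors (default 5, capped at n/10) excluded within a 10-cM window of the
test position, gives `LOD = (n/2)·log₁₀(RSS₀/RSS₁)`. With zero cofactors
this reproduces simple interval mapping exactly (tested to 1e−8). Dosage is
coded −1/+1 so the fitted coefficient is half the homozygote difference;
flipping parental labels flips every effect sign and nothing else.

Thresholds are genome-wide phenotype permutations (cofactors re-selected per
permutation; default 1000 at α = 0.05, empirical order-statistic quantile,
slightly conservative by construction). QTL are peaks above threshold with
1.5-LOD support intervals, separated by at least the support width or a
sub-threshold valley; PVE comes from a single-QTL fit at the peak; bp ↔ cM
conversion is piecewise linear between mapped markers. QTL names follow the
environment-letter / stage-letter / population-letter / chromosome code, and
pleiotropic QTL merge physical support intervals transitively per chromosome
(A–B and B–C overlapping put A, B, C in one merged region even if A and C are
disjoint), reporting the union span and its length in Mb to 2 decimals.

A design note on the single-QTL recovery benchmark: the recovery experiment
scans with zero cofactors. Its architecture has exactly one QTL, so there is
no background signal for CIM cofactors to absorb — noise cofactors on the
QTL chromosome only blur localization (measured: 0.91 vs 0.80 of peaks within
±5 cM at PVE 10%, H² 0.7, n = 200). The multi-QTL cofactor-absorption
property is tested separately, where CIM beats simple interval mapping in
≥ 80% of simulations.

## GBLUP models and the Gibbs sampler

Kernels: VanRaden `G = ZZ′/(2Σp_j(1−p_j))` with per-marker mean imputation
before centering; auxiliary kernel `G_v = n·M_vM_v′/trace(M_vM_v′)` from
standardized (population-SD) auxiliary phenotype columns, so trace(G_v) = n
exactly. The FIXED model moves QTL-peak marker dosages into fixed effects and
rebuilds G from the remaining m − p markers.

The sampler reparameterises each kernel by its eigen square root
(`u = U√S a`, `a ~ N(0, σ²I)`, near-null eigenvalues dropped at 1e−8) and
then rotates `a` by the eigenvectors of the training-block normal-equations
matrix, making every conditional draw elementwise — an exact Gibbs scheme at
O(nk) per sweep. Variance components get scaled-inverse-χ² priors with 5
degrees of freedom and scales set from an R² = 0.5 variance split divided
equally among kernels. Defaults are 10,000 iterations with 5,000 burn-in;
posterior-mean GEBVs correlate > 0.99 with deterministic mixed-model-equation
BLUPs at the REML variance ratio.

Cross-validation uses uniform random (unstratified) fold partitions, 5 folds,
with every replicate's seed logged. Test-fold phenotypes of the *target*
trait are masked; auxiliary kernels legitimately use all individuals' other
environment/stage phenotypes. `r_MP` correlates test GEBVs with raw observed
phenotypes (per-line means), and the FIXED model's predictions include Xβ̂
for test individuals since their marker genotypes are known. A fold with
constant predictions records r_MP = 0 with a warning.

## Problem sizes for the benchmark studies

The evaluation studies in `rindqtl.experiments` use: 2–3 chromosomes of
100–120 cM with 51–76 markers; n = 100–250 lines; 100 populations for peak
recovery; 200 simulations for estimator unbiasedness; 60 null traits × 200
permutations for threshold calibration; and 20 CV replicates with shortened
Gibbs chains (2,000/500) for the four-model comparison — sizes chosen to keep
each study in the seconds-to-minutes range on one core while leaving the
statistical comparisons well powered. The model-comparison design gives the
target trait one major QTL (30% of entry-mean variance, total h² 0.6), two
auxiliary environments sharing its genetic values, and six auxiliary stages
correlated 0.8 with them.

## Known limitations

- The F∞ Markov shortcut is exact pairwise but not a full multi-locus RIL
  process; higher-order haplotype frequencies differ slightly from explicit
  selfing.
- Moment estimators require balanced tables; unbalanced data are supported
  only through the GLS BLUE path with supplied components.
- The CIM cofactor count/window and LOD-drop defaults are conventions, not
  optimized values; they are recorded in run manifests.
- Binary traits (e.g. color validation scans) are handled as ordinary
  quantitative scans on 0/1 phenotypes.
- No multi-QTL model selection, epistasis scan, or GxE reaction-norm kernels.
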